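"""On-off-keyed signalling over the puff channel.

A bit 1 is an instantaneous bolus of ``m_per_pulse`` mg released at the
start of its slot; a bit 0 is silence.  Frames are header ++ payload ++
trailer (defaults: "11" ++ 10 bits ++ "00000", 0.5 s slots).  The receiver
integrates uptake per slot — including the tails of earlier releases, the
inter-symbol interference inherent to a dispersive channel — optionally adds
Poisson counting noise, and thresholds: bit 1 iff the slot quantity is >=
m_th (boundary inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dispersion import Environment, SourceEvent, DispersionScheme, \
    FieldOptions, PASQUILL_F_PRINTED
from .uptake import ReceiverSphere, QuadratureSpec, received_quantity_window

__all__ = [
    "FrameSpec",
    "LinkConfig",
    "encode_frame",
    "decode_frame",
    "modulate_ook",
    "demodulate_threshold",
    "slot_response",
    "per_slot_quantities",
    "ber_monte_carlo",
]


@dataclass(frozen=True)
class FrameSpec:
    """Frame layout and slot timing."""

    header: str = "11"
    payload_len: int = 10
    trailer: str = "00000"
    slot: float = 0.5        # s
    pulse: float = 0.1       # s (atomizer on-time; idealized as a bolus)

    def __post_init__(self) -> None:
        if set(self.header + self.trailer) - {"0", "1"}:
            raise ValueError("header/trailer must be bit strings")
        if self.payload_len <= 0:
            raise ValueError("payload_len must be positive")
        if self.slot <= 0 or self.pulse <= 0:
            raise ValueError("slot and pulse must be positive")

    @property
    def frame_len(self) -> int:
        return len(self.header) + self.payload_len + len(self.trailer)

    def replace(self, **kw) -> "FrameSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class LinkConfig:
    """Per-pulse mass, detection threshold and reception-noise model."""

    m_per_pulse: float = 0.0016     # mg
    m_th: float = 0.0               # threshold, same units as slot quantity
    noise_model: str = "none"       # none | poisson
    counts_per_unit: float = 1.0    # counts per (mg s) for poisson noise

    def __post_init__(self) -> None:
        if self.m_th < 0:
            raise ValueError("m_th must be non-negative")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError("noise_model must be 'none' or 'poisson'")
        if self.counts_per_unit <= 0:
            raise ValueError("counts_per_unit must be positive")

    def replace(self, **kw) -> "LinkConfig":
        return replace(self, **kw)


def _as_bits(bits) -> list[int]:
    if isinstance(bits, str):
        seq = bits
    else:
        seq = "".join(str(int(b)) for b in bits)
    if set(seq) - {"0", "1"}:
        raise ValueError("bit sequence must contain only 0/1")
    return [int(c) for c in seq]


def encode_frame(payload, spec: FrameSpec = FrameSpec()) -> str:
    """header ++ payload ++ trailer (17 bits with the defaults)."""
    p = _as_bits(payload)
    if len(p) != spec.payload_len:
        raise ValueError(f"payload must be {spec.payload_len} bits, "
                         f"got {len(p)}")
    return spec.header + "".join(map(str, p)) + spec.trailer


def decode_frame(bits, spec: FrameSpec = FrameSpec()):
    """Payload string, or None on sync failure (bad length, header or
    trailer)."""
    try:
        b = "".join(map(str, _as_bits(bits)))
    except ValueError:
        return None
    if len(b) != spec.frame_len:
        return None
    if not b.startswith(spec.header) or not b.endswith(spec.trailer):
        return None
    return b[len(spec.header):len(spec.header) + spec.payload_len]


def modulate_ook(bits, spec: FrameSpec = FrameSpec(),
                 link: LinkConfig = LinkConfig()) -> list[tuple]:
    """Emission schedule [(release time s, mass mg), ...]: one bolus at each
    1-slot start, nothing for 0-slots."""
    return [(i * spec.slot, link.m_per_pulse)
            for i, b in enumerate(_as_bits(bits)) if b == 1]


def demodulate_threshold(per_slot_quantity, m_th: float) -> str:
    """Threshold decision per slot; the boundary counts as a detection
    (quantity >= m_th -> bit 1)."""
    if m_th < 0:
        raise ValueError("m_th must be non-negative")
    q = np.asarray(per_slot_quantity, dtype=float)
    return "".join("1" if v >= m_th else "0" for v in q)


def slot_response(spec: FrameSpec = FrameSpec(),
                  link: LinkConfig = LinkConfig(),
                  rx: ReceiverSphere = ReceiverSphere(),
                  src: SourceEvent = SourceEvent(),
                  env: Environment = Environment(),
                  scheme: DispersionScheme = PASQUILL_F_PRINTED,
                  opts: FieldOptions = FieldOptions(),
                  quad: QuadratureSpec = QuadratureSpec(),
                  n_slots: int | None = None) -> np.ndarray:
    """g[k]: received quantity in slot k from one pulse released at slot 0.

    By time invariance this single vector determines every slot quantity of
    an arbitrary bit stream by superposition.  The vector is truncated once
    the tail is negligible (or at ``n_slots``).
    """
    src = src.replace(m=link.m_per_pulse, t0=0.0)
    g = []
    k = 0
    max_slots = n_slots if n_slots is not None else 64
    while k < max_slots:
        q = received_quantity_window(
            rx.replace(tau=(k + 1) * spec.slot), src, env, scheme, opts, quad,
            window=(k * spec.slot, (k + 1) * spec.slot))
        g.append(q)
        k += 1
        if n_slots is None and k >= 2 and q <= 1e-9 * max(g[0], 1e-300):
            break
    return np.asarray(g)


def per_slot_quantities(bits, g: np.ndarray) -> np.ndarray:
    """Noiseless slot quantities of a bit stream: discrete convolution of the
    bit indicator with the single-pulse slot response (superposition)."""
    b = np.asarray(_as_bits(bits), dtype=float)
    return np.convolve(b, g)[: b.size]


def ber_monte_carlo(spec: FrameSpec = FrameSpec(),
                    link: LinkConfig = LinkConfig(),
                    *,
                    rx: ReceiverSphere = ReceiverSphere(),
                    src: SourceEvent = SourceEvent(),
                    env: Environment = Environment(),
                    scheme: DispersionScheme = PASQUILL_F_PRINTED,
                    opts: FieldOptions = FieldOptions(),
                    quad: QuadratureSpec = QuadratureSpec(),
                    n_frames: int = 10,
                    seed: int = 0):
    """Bit error rate over random-payload frames.

    Returns (ber, table) where the table holds per-slot sent bits, received
    quantities (with noise, if any) and decisions.  Deterministic given
    ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    g = slot_response(spec, link, rx, src, env, scheme, opts, quad)
    errors = 0
    total = 0
    records = []
    for fr in range(n_frames):
        payload = "".join(rng.choice(["0", "1"], size=spec.payload_len))
        sent = encode_frame(payload, spec)
        q = per_slot_quantities(sent, g)
        if link.noise_model == "poisson":
            counts = rng.poisson(q * link.counts_per_unit)
            q_obs = counts / link.counts_per_unit
        else:
            q_obs = q
        decided = demodulate_threshold(q_obs, link.m_th)
        errors += sum(a != b for a, b in zip(sent, decided))
        total += len(sent)
        for i, (b, qv, d) in enumerate(zip(sent, q_obs, decided)):
            records.append((fr, i, int(b), qv, int(d)))
    table = pd.DataFrame(records, columns=["frame", "slot", "sent_bit",
                                           "quantity", "decided_bit"])
    return errors / total, table
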