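"""Synthetic long-read pairs with per-base substitution/indel noise.

The generator emulates pairs of long reads (1-30 kbp) covering the same
molecule: an ancestor sequence is drawn uniformly over {A,C,G,T}, and each
read is an independently mutated copy where every ancestor base suffers
exactly one event drawn from an :class:`~banddp.band_model.ErrorProfile`:

* ``keep``        (p_u) -- the base is emitted unchanged;
* ``substitute``  (p_m) -- a uniformly chosen *different* base is emitted;
* ``insert``      (p_i) -- the base is emitted, followed by one uniform
  random base (after-position convention);
* ``delete``      (p_d) -- nothing is emitted.

Indels are single-base events; there is no length distribution, no
homopolymer bias and no quality model.  Every pair carries a
:class:`MutationLog` per read, and replaying a log over the ancestor
reproduces the read exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

from .band_model import ErrorProfile

_BASES = np.frombuffer(b"ACGT", np.uint8)

KEEP, SUB, INS, DEL = 0, 1, 2, 3
_EVENT_NAMES = ("keep", "substitute", "insert", "delete")

Pairing = Literal["both_mutated", "one_mutated"]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(256, np.uint8)
    for i, c in enumerate(b"ACGT"):
        lut[c] = i
    return lut[np.frombuffer(seq.encode("ascii"), np.uint8)]


@dataclass
class MutationLog:
    """Ground-truth edit events for one mutated copy.

    Stored compactly as parallel arrays over ancestor positions: the event
    code, the substituted base (valid where event == SUB) and the inserted
    base (valid where event == INS).
    """

    event: np.ndarray       # uint8, one code per ancestor position
    sub_base: np.ndarray    # uint8 codes, aligned with `event`
    ins_base: np.ndarray    # uint8 codes, aligned with `event`

    @property
    def n_sub(self) -> int:
        return int(np.count_nonzero(self.event == SUB))

    @property
    def n_ins(self) -> int:
        return int(np.count_nonzero(self.event == INS))

    @property
    def n_del(self) -> int:
        return int(np.count_nonzero(self.event == DEL))

    def events(self, ancestor: str) -> Iterator[tuple[int, str, str]]:
        """Yield (ancestor position, event name, emitted bases)."""
        for pos, ev in enumerate(self.event):
            if ev == KEEP:
                emitted = ancestor[pos]
            elif ev == SUB:
                emitted = _decode(self.sub_base[pos:pos + 1])
            elif ev == INS:
                emitted = ancestor[pos] + _decode(self.ins_base[pos:pos + 1])
            else:
                emitted = ""
            yield pos, _EVENT_NAMES[ev], emitted


@dataclass
class SimulatedPair:
    """A simulated read pair plus full provenance."""

    seq_a: str
    seq_b: str
    ancestor: str
    log_a: "MutationLog | None"
    log_b: MutationLog
    profile: ErrorProfile
    seed: object


def random_sequence(N: int, seed) -> str:
    """i.i.d. uniform A/C/G/T string of length N, deterministic per seed."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    return _decode(rng.integers(0, 4, size=N, dtype=np.uint8))


def _apply(codes: np.ndarray, log: MutationLog) -> np.ndarray:
    """Replay a mutation log over encoded ancestor bases."""
    ev = log.event
    emit = np.where(ev == DEL, 0, np.where(ev == INS, 2, 1))
    start = np.cumsum(emit) - emit
    out = np.empty(int(emit.sum()), np.uint8)
    keep_or_ins = (ev == KEEP) | (ev == INS)
    out[start[keep_or_ins]] = codes[keep_or_ins]
    is_sub = ev == SUB
    out[start[is_sub]] = log.sub_base[is_sub]
    is_ins = ev == INS
    out[start[is_ins] + 1] = log.ins_base[is_ins]
    return out


def mutate(seq: str, profile: ErrorProfile, seed) -> tuple[str, MutationLog]:
    """Mutate a sequence base by base according to the error profile."""
    rng = np.random.default_rng(seed)
    codes = _encode(seq)
    N = codes.size
    u = rng.random(N)
    p_u, p_m, p_i, _ = profile.as_tuple()
    event = np.full(N, DEL, np.uint8)
    event[u < p_u + p_m + p_i] = INS
    event[u < p_u + p_m] = SUB
    event[u < p_u] = KEEP
    # substituted base: uniformly one of the three *other* bases
    sub_base = ((codes + rng.integers(1, 4, size=N, dtype=np.uint8)) % 4
                ).astype(np.uint8)
    ins_base = rng.integers(0, 4, size=N, dtype=np.uint8)
    log = MutationLog(event=event, sub_base=sub_base, ins_base=ins_base)
    return _decode(_apply(codes, log)), log


def replay(ancestor: str, log: MutationLog) -> str:
    """Re-derive the mutated sequence from the ancestor and its log."""
    return _decode(_apply(_encode(ancestor), log))


def make_pair(N: int, profile: ErrorProfile, seed,
              pairing: Pairing = "both_mutated") -> SimulatedPair:
    """Generate one read pair.

    ``both_mutated``: both reads are independent mutated copies of one
    random ancestor (each read contributes its own indels, as two
    sequencing passes over the same molecule would).  ``one_mutated``:
    seq_a *is* the ancestor and only seq_b is mutated.  Three child
    streams are spawned from the seed so the two modes share the same
    ancestor for a given seed.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_anc, s_a, s_b = ss.spawn(3)
    ancestor = random_sequence(N, s_anc)
    if pairing == "both_mutated":
        seq_a, log_a = mutate(ancestor, profile, s_a)
    elif pairing == "one_mutated":
        seq_a, log_a = ancestor, None
    else:
        raise ValueError(f"unknown pairing mode: {pairing!r}")
    seq_b, log_b = mutate(ancestor, profile, s_b)
    return SimulatedPair(seq_a=seq_a, seq_b=seq_b, ancestor=ancestor,
                         log_a=log_a, log_b=log_b, profile=profile, seed=seed)


def pair_stream(N: int, profile: ErrorProfile, n_pairs: int, seed,
                pairing: Pairing = "both_mutated") -> Iterator[SimulatedPair]:
    """Independent, reproducible pairs: one child seed per pair index."""
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    for child in root.spawn(n_pairs):
        yield make_pair(N, profile, child, pairing)
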