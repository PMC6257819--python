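"""Cycling-sequence task design: chunks, sequences, counterbalanced schedules.

The task is an explicit sequencing paradigm: participants memorize a sequence of
line orientations organized into 3-element chunks and then cycle through it,
one match/mismatch probe judgment per trial.  Four "control codes" label every
trial: the element itself (which orientation), its ordinal position within the
chunk, the identity of the chunk, and the position of the chunk within the
sequence.  The designs counterbalance these codes fully across blocks so that
each can be decoded independently of the others.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three basic elements, encoded A/B/C; they stand for line orientations.
ELEMENTS = ("A", "B", "C")

#: Orientation (degrees) of each element.
ORIENTATION_DEG = {"A": 45, "B": 90, "C": 135}

#: Chunk pools. Experiments 1/2 use the three cyclic rotations; Experiment 3
#: uses all six permutations of the three elements.
EXP12_CHUNKS = ("ABC", "BCA", "CAB")
EXP3_CHUNKS = ("ABC", "ACB", "BAC", "BCA", "CAB", "CBA")


class InvalidDesignError(ValueError):
    """Raised when a task design is internally inconsistent."""


class BalanceError(ValueError):
    """Raised when a schedule cannot balance sequences over blocks."""


@dataclass(frozen=True)
class Chunk:
    """An ordered triple of distinct elements, e.g. ``Chunk("ABC")``."""

    label: str

    def __post_init__(self):
        if len(self.label) != 3 or len(set(self.label)) != 3:
            raise InvalidDesignError(
                f"chunk {self.label!r} must be 3 distinct elements"
            )
        if any(e not in ELEMENTS for e in self.label):
            raise InvalidDesignError(f"chunk {self.label!r} uses unknown elements")

    @property
    def elements(self) -> tuple[str, str, str]:
        return tuple(self.label)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design constants of one experiment variant.

    ``boundary_rule`` controls which chunk orders form legal sequences:
    ``"none"`` allows every order; ``"cyclic_no_repeat"`` forbids an element
    repeating at any chunk junction, including the wrap-around junction from
    the last chunk back to the first (sequences cycle within a block).
    """

    variant: str
    chunk_pool: tuple[Chunk, ...]
    chunks_per_sequence: int
    cycles_per_block: int
    n_blocks: int
    boundary_rule: str = "none"
    prep_ms: int = 1250

    def __post_init__(self):
        if not self.chunk_pool:
            raise InvalidDesignError("chunk pool is empty")
        if self.chunks_per_sequence < 1:
            raise InvalidDesignError("chunks_per_sequence must be >= 1")
        if self.boundary_rule not in ("none", "cyclic_no_repeat"):
            raise InvalidDesignError(f"unknown boundary rule {self.boundary_rule!r}")

    @property
    def sequence_length(self) -> int:
        return 3 * self.chunks_per_sequence

    @property
    def trials_per_block(self) -> int:
        return self.cycles_per_block * self.sequence_length

    @classmethod
    def from_variant(cls, variant: str, n_blocks: int | None = None) -> "ExperimentDesign":
        """Canonical designs: exp1/exp2 (9-element, 3 chunks x 6 cycles x 24
        blocks), exp3 (6-element, 2 chunks x 7 cycles x 36 blocks)."""
        if variant in ("exp1", "exp2"):
            return cls(
                variant=variant,
                chunk_pool=tuple(Chunk(c) for c in EXP12_CHUNKS),
                chunks_per_sequence=3,
                cycles_per_block=6,
                n_blocks=24 if n_blocks is None else n_blocks,
                boundary_rule="none",
                prep_ms=1250 if variant == "exp1" else 1100,
            )
        if variant == "exp3":
            return cls(
                variant=variant,
                chunk_pool=tuple(Chunk(c) for c in EXP3_CHUNKS),
                chunks_per_sequence=2,
                cycles_per_block=7,
                n_blocks=36 if n_blocks is None else n_blocks,
                boundary_rule="cyclic_no_repeat",
                prep_ms=1000,
            )
        raise InvalidDesignError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class Sequence:
    """An ordered list of chunks plus the derived per-step control codes."""

    chunks: tuple[Chunk, ...]

    @property
    def label(self) -> str:
        return "-".join(c.label for c in self.chunks)

    @property
    def steps(self) -> list[dict]:
        """One dict per serial step with the four control codes."""
        out = []
        for chunk_pos, chunk in enumerate(self.chunks, start=1):
            for within_pos, element in enumerate(chunk.elements, start=1):
                out.append(
                    {
                        "element": element,
                        "within_chunk_position": within_pos,
                        "chunk_identity": chunk.label,
                        "chunk_position": chunk_pos,
                    }
                )
        return out

    def __len__(self) -> int:
        return 3 * len(self.chunks)


def _junction_ok(chunks: tuple[Chunk, ...], rule: str) -> bool:
    if rule == "none":
        return True
    # cyclic_no_repeat: adjacent elements must differ at every junction,
    # including the wrap-around junction formed when the sequence cycles.
    n = len(chunks)
    for i in range(n):
        if chunks[i].elements[-1] == chunks[(i + 1) % n].elements[0]:
            return False
    return True


def enumerate_sequences(design: ExperimentDesign) -> list[Sequence]:
    """All legal sequences of ``chunks_per_sequence`` distinct pool chunks.

    Returns sequences in canonical (lexicographic on chunk labels) order, so
    the enumeration is deterministic.  The exp1/2 design yields 6 sequences;
    the exp3 design yields 12 (the cyclic no-repeat rule removes 18 of the 30
    ordered pairs' wrap-around or internal repeats).
    """
    seqs = [
        Sequence(chunks=perm)
        for perm in itertools.permutations(design.chunk_pool, design.chunks_per_sequence)
        if _junction_ok(perm, design.boundary_rule)
    ]
    seqs.sort(key=lambda s: s.label)
    return seqs


SCHEDULE_COLUMNS = [
    "subject",
    "block",
    "cycle",
    "serial_index",
    "sequence",
    "element",
    "within_chunk_position",
    "chunk_identity",
    "chunk_position",
    "probe_orientation",
    "is_match",
]


def build_schedule(
    design: ExperimentDesign,
    seed: int,
    subject: int = 0,
    allow_unbalanced: bool = False,
) -> pd.DataFrame:
    """Build a per-trial schedule for one subject.

    Each block presents one sequence, cycled ``cycles_per_block`` times.  The
    sequence-to-block assignment uses every legal sequence equally often, in a
    seeded random order; this is what guarantees the counterbalancing of the
    four control codes across a session.

    Returns a DataFrame with one row per trial (``SCHEDULE_COLUMNS``); probe
    columns are filled by :func:`assign_probes`.
    """
    rng = np.random.default_rng(seed)
    seqs = enumerate_sequences(design)
    n_seq = len(seqs)
    if design.n_blocks % n_seq and not allow_unbalanced:
        raise BalanceError(
            f"{design.n_blocks} blocks cannot use {n_seq} sequences equally often; "
            "pass allow_unbalanced=True to override"
        )
    reps = -(-design.n_blocks // n_seq)  # ceil
    order = np.tile(np.arange(n_seq), reps)[: design.n_blocks]
    rng.shuffle(order)

    rows = []
    for block, seq_ix in enumerate(order):
        seq = seqs[seq_ix]
        steps = seq.steps
        L = len(steps)
        for k in range(design.trials_per_block):
            step = steps[k % L]
            rows.append(
                {
                    "subject": subject,
                    "block": block,
                    "cycle": k // L,
                    "serial_index": k,
                    "sequence": seq.label,
                    **step,
                    "probe_orientation": None,
                    "is_match": None,
                }
            )
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def assign_probes(schedule: pd.DataFrame, p_match: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Draw a match/mismatch probe for every trial.

    With probability ``p_match`` the probe equals the trial's element;
    otherwise it is drawn uniformly from the two other orientations.  Returns
    a copy; seeded-reproducible.
    """
    if not 0.0 <= p_match <= 1.0:
        raise ValueError("p_match must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    n = len(out)
    match = rng.random(n) < p_match
    elements = out["element"].to_numpy()
    probes = elements.copy()
    for i in np.flatnonzero(~match):
        others = [e for e in ELEMENTS if e != elements[i]]
        probes[i] = others[rng.integers(2)]
    out["probe_orientation"] = probes
    out["is_match"] = match
    return out


@dataclass(frozen=True)
class WMScore:
    """Change-detection working-memory capacity: K = S * (H - F)."""

    S: int
    H: float
    F: float
    K: float = field(init=False)

    def __post_init__(self):
        if self.S <= 0:
            raise ValueError("set size S must be positive")
        for name, v in (("H", self.H), ("F", self.F)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a rate in [0, 1]")
        object.__setattr__(self, "K", self.S * (self.H - self.F))


def cowans_k(S: int, H: float, F: float) -> WMScore:
    """Cowan's K capacity estimate from a change-detection task."""
    return WMScore(S=S, H=H, F=F)


def median_split_wm(scores, tie_group: str = "low") -> np.ndarray:
    """Split subjects into high/low WM-capacity groups at the median K.

    ``scores`` may be floats or :class:`WMScore`.  Subjects exactly at the
    median go to ``tie_group`` (default low).  Emits a warning when all scores
    are equal (degenerate split).
    """
    ks = np.asarray([s.K if isinstance(s, WMScore) else float(s) for s in scores])
    if ks.size < 2:
        raise ValueError("median split needs at least 2 subjects")
    if np.all(ks == ks[0]):
        warnings.warn("all K equal: median split is degenerate", stacklevel=2)
    med = np.median(ks)
    if tie_group == "low":
        labels = np.where(ks > med, "high", "low")
    else:
        labels = np.where(ks >= med, "high", "low")
    return labels


def schedule_to_csv(schedule: pd.DataFrame, path) -> None:
    """Serialize a trial schedule as delimited text (one row per trial)."""
    schedule.to_csv(path, index=False)


def schedule_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
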