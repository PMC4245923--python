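"""Tiling probe design with melting-temperature-driven length adjustment.

The array carries a complete overlapping probe set: every position of every
allele anchors one probe (shifted by a single nucleotide).  Starting from a
25-mer at each anchor, the probe is extended or shortened at its 3' end until
its melting temperature is as close as possible to the hybridization target of
64.2 degC, within the synthesis bounds of 20-60 nt.  Identical probe sequences
arising from different alleles are deduplicated into unique probes; the probe
set records every (allele, start) placement of each unique probe, which is how
probe masking (a probe of an absent allele lighting up because the same
sequence occurs in a present allele) enters the calling stages downstream.

Tm uses the GC-count rule for long oligos::

    Tm = 64.9 + 41 * (nG + nC - 16.4) / length
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import AlleleCatalog, AlleleSequence, validate_dna
from .errors import CatalogError, PositionError

DEFAULT_TARGET_TM = 64.2
DEFAULT_MIN_LEN = 20
DEFAULT_MAX_LEN = 60
INITIAL_LENGTH = 25


def melting_temperature(probe_sequence: str) -> float:
    """Melting temperature (degC) of a probe from its base composition."""
    validate_dna(probe_sequence)
    gc = probe_sequence.count("G") + probe_sequence.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(probe_sequence)


@dataclass(frozen=True)
class Probe:
    """A designed probe anchored on a source allele."""

    sequence: str
    source_allele: str
    start: int
    length: int
    tm: float

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("probe length field disagrees with sequence")


def tile_initial_probes(allele: AlleleSequence, initial_length: int = INITIAL_LENGTH) -> list[Probe]:
    """The starting overlapping set: one ``initial_length``-mer per position.

    Consecutive probes overlap by ``initial_length - 1`` nucleotides.
    """
    n = len(allele.sequence)
    if n < initial_length:
        raise PositionError(
            f"{allele.name}: sequence length {n} shorter than initial probe length {initial_length}"
        )
    probes = []
    for start in range(n - initial_length + 1):
        seq = allele.sequence[start : start + initial_length]
        probes.append(Probe(seq, allele.name, start, initial_length, melting_temperature(seq)))
    return probes


def adjust_probe_length(
    allele: AlleleSequence,
    start: int,
    target_tm: float = DEFAULT_TARGET_TM,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> Probe:
    """Pick the probe length at ``start`` whose Tm is closest to ``target_tm``.

    The search runs over lengths ``min_len .. min(max_len, remaining)``;
    ties in \\|Tm - target\\| are broken toward the shorter probe.  Adjustment is
    one-sided: the anchor (5' start) is fixed and the 3' end moves, so the
    probe signal can keep being assigned to its starting position.
    """
    n = len(allele.sequence)
    if start < 0 or start + min_len > n:
        raise PositionError(
            f"{allele.name}: no probe of length >= {min_len} fits at start {start} (sequence length {n})"
        )
    best: Probe | None = None
    best_diff = np.inf
    for length in range(min_len, min(max_len, n - start) + 1):
        seq = allele.sequence[start : start + length]
        tm = melting_temperature(seq)
        diff = abs(tm - target_tm)
        if diff < best_diff:
            best, best_diff = Probe(seq, allele.name, start, length, tm), diff
    assert best is not None
    return best


def _design_allele(seq: str, target_tm: float, min_len: int, max_len: int) -> np.ndarray:
    """Vectorized per-anchor optimal lengths for one allele sequence."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
    anchors = np.arange(n - min_len + 1)
    lengths = np.arange(min_len, max_len + 1)
    ends = anchors[:, None] + lengths[None, :]
    feasible = ends <= n
    gc = gc_cum[np.minimum(ends, n)] - gc_cum[anchors][:, None]
    tm = 64.9 + 41.0 * (gc - 16.4) / lengths[None, :]
    diff = np.abs(tm - target_tm)
    diff[~feasible] = np.inf
    # argmin over ascending lengths -> ties resolve to the shorter probe
    return lengths[np.argmin(diff, axis=1)]


class ProbeSet:
    """Deduplicated unique probes plus their placements across a catalog.

    Attributes
    ----------
    sequences : list of unique probe sequences; the index is the probe id.
    lengths, tm : per-probe arrays parallel to ``sequences``.
    allele_probes : allele name -> int array of probe ids, indexed by anchor
        (position 0 .. len(allele) - min_len).  This is the per-allele probe
        track used by error correction and the win-counting comparisons.
    replicates : physical replicate count per probe (the array printed some
        probes more than once; modeled as a count, not repeated entries).
    """

    def __init__(
        self,
        sequences: list[str],
        allele_probes: dict[str, np.ndarray],
        target_tm: float = DEFAULT_TARGET_TM,
        min_len: int = DEFAULT_MIN_LEN,
        max_len: int = DEFAULT_MAX_LEN,
        replicates: np.ndarray | None = None,
    ):
        self.sequences = sequences
        self.allele_probes = allele_probes
        self.target_tm = target_tm
        self.min_len = min_len
        self.max_len = max_len
        self.lengths = np.array([len(s) for s in sequences], dtype=np.int64)
        self.tm = np.array([melting_temperature(s) for s in sequences]) if sequences else np.empty(0)
        self.replicates = (
            replicates if replicates is not None else np.ones(len(sequences), dtype=np.int64)
        )

    @property
    def n_probes(self) -> int:
        return len(self.sequences)

    @property
    def n_placements(self) -> int:
        return sum(len(v) for v in self.allele_probes.values())

    def coverage(self) -> dict[int, list[tuple[str, int]]]:
        """Inverse map: probe id -> every (allele, start) placement."""
        cov: dict[int, list[tuple[str, int]]] = {pid: [] for pid in range(self.n_probes)}
        for allele, pids in self.allele_probes.items():
            for start, pid in enumerate(pids):
                cov[int(pid)].append((allele, start))
        return cov

    def per_allele_index(self) -> dict[str, list[int]]:
        return {a: [int(p) for p in pids] for a, pids in self.allele_probes.items()}

    @property
    def fingerprint(self) -> str:
        """Hash binding dependent artifacts (signals, knowledgebases) to this design."""
        h = hashlib.sha256()
        h.update(f"{self.target_tm}:{self.min_len}:{self.max_len}:".encode())
        for s in self.sequences:
            h.update(s.encode())
            h.update(b"\n")
        return h.hexdigest()

    # -- tables ----------------------------------------------------------
    def probe_frame(self) -> pd.DataFrame:
        counts = np.zeros(self.n_probes, dtype=np.int64)
        for pids in self.allele_probes.values():
            np.add.at(counts, pids, 1)
        return pd.DataFrame(
            {
                "probe_id": np.arange(self.n_probes),
                "sequence": self.sequences,
                "length": self.lengths,
                "tm": self.tm,
                "n_placements": counts,
            }
        )

    def placement_frame(self) -> pd.DataFrame:
        rows = []
        for allele, pids in self.allele_probes.items():
            for start, pid in enumerate(pids):
                rows.append((int(pid), allele, start))
        return pd.DataFrame(rows, columns=["probe_id", "allele", "start"])


def build_probe_set(
    catalog: AlleleCatalog,
    target_tm: float = DEFAULT_TARGET_TM,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> ProbeSet:
    """Tile and Tm-adjust every position of every allele, then deduplicate.

    Every anchor 0 .. len-min_len of every allele yields exactly one placement;
    anchors with fewer than ``min_len`` nucleotides remaining anchor nothing.
    """
    if min_len < 1 or max_len < min_len:
        raise CatalogError(f"invalid probe length bounds [{min_len}, {max_len}]")
    seq_to_id: dict[str, int] = {}
    sequences: list[str] = []
    allele_probes: dict[str, np.ndarray] = {}
    for allele in catalog:
        seq = allele.sequence
        best_lengths = _design_allele(seq, target_tm, min_len, max_len)
        pids = np.empty(len(best_lengths), dtype=np.int64)
        for start, length in enumerate(best_lengths):
            probe_seq = seq[start : start + length]
            pid = seq_to_id.get(probe_seq)
            if pid is None:
                pid = len(sequences)
                seq_to_id[probe_seq] = pid
                sequences.append(probe_seq)
            pids[start] = pid
        allele_probes[allele.name] = pids
    return ProbeSet(sequences, allele_probes, target_tm, min_len, max_len)
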