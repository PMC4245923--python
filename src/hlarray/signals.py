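"""Array signal processing: normalization, error correction, thresholding, QC.

Raw fluorescence ranges vary widely between slides, so every array is mapped
onto a fixed scale (min 1, mean 1,000, max capped at 20,000) with the linear
transformation

    Sn = min(S - Rmin + F, F * 20000) / F

where Rmin is the array minimum and the scaling factor F is solved so that the
mean of the normalized signals equals 1,000.  Because positive signals change
smoothly along the overlapping-probe track of each allele while negative
probes sit at background, isolated spikes or dropouts can be detected against
a rolling window median and corrected.  Positivity is decided per probe by an
allele-specific threshold: 10% of the maximal signal to start with, refined
empirically once a knowledgebase of typed arrays accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import brentq
from scipy.stats import pearsonr

from .errors import ConfigError, DegenerateArrayError, SignalInputError
from .probes import ProbeSet

SCALE_MIN = 1.0
SCALE_MEAN = 1000.0
SCALE_MAX = 20000.0
DEFAULT_INITIAL_FRACTION = 0.10
DEFAULT_DEGRADED_RATIO = 1.0 / 3.0


@dataclass
class ArraySignals:
    """Per-probe signal vector for one array.

    ``values[i]`` is the signal of probe id ``i`` in a fixed canonical probe
    order (the ProbeSet order).  ``raw_mean`` keeps the raw-scale array mean
    through normalization because QC (degradation flagging) is defined on the
    raw scale.
    """

    array_id: str
    stage: str  # 'raw' | 'normalized' | 'corrected'
    values: np.ndarray
    raw_mean: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean_signal(self) -> float:
        return float(self.values.mean())

    @property
    def n_probes(self) -> int:
        return self.values.size


def read_signals_tsv(path, array_id: str | None = None, stage: str = "raw") -> ArraySignals:
    """Read a two-column (probe_id, signal) TSV, as emitted by feature extraction."""
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "signal"}.issubset(df.columns):
        raise SignalInputError(f"{path}: expected columns probe_id, signal")
    df = df.sort_values("probe_id")
    values = np.zeros(int(df["probe_id"].max()) + 1)
    values[df["probe_id"].to_numpy()] = df["signal"].to_numpy()
    if array_id is None:
        import os

        array_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ArraySignals(array_id, stage, values)


def write_signals_tsv(signals: ArraySignals, path) -> None:
    pd.DataFrame(
        {"probe_id": np.arange(signals.n_probes), "signal": signals.values}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_signals(
    raw: ArraySignals,
    target_mean: float = SCALE_MEAN,
    cap: float = SCALE_MAX,
    rel_tol: float = 1e-6,
) -> ArraySignals:
    """Map raw signals onto the 1..cap scale with array mean = ``target_mean``.

    The capped formula does not pin F in closed form, so F is defined as the
    unique root of mean(Sn(F)) = target_mean: mean(Sn) is strictly decreasing
    in F while any uncapped above-minimum signal exists, so bisection
    (Brent's method) on a bracketing interval converges to machine precision.
    When no probe hits the cap the closed form F = mean(S - Rmin)/(target - 1)
    is exact and is used directly.
    """
    v = np.asarray(raw.values, dtype=float)
    if v.size < 2:
        raise SignalInputError("normalization requires at least 2 probes")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise SignalInputError("raw signals must be positive and finite")
    rmin = float(v.min())
    d = v - rmin
    if not np.any(d > 0):
        raise DegenerateArrayError("constant raw signal vector: no scaling factor exists")

    def mean_sn(f: float) -> float:
        return float(np.minimum(d / f + 1.0, cap).mean())

    f0 = float(d.mean()) / (target_mean - SCALE_MIN)
    if mean_sn(f0) == target_mean:  # cap inactive: closed form exact
        f = f0
    else:
        # mean(Sn) decreases in F; bracket the root around the uncapped
        # closed-form F (capping can leave it on either side numerically)
        lo = hi = f0
        for _ in range(200):
            if mean_sn(lo) > target_mean:
                break
            lo /= 2.0
        else:
            raise DegenerateArrayError(
                "array mean cannot reach the target: too much mass at the minimum"
            )
        for _ in range(200):
            if mean_sn(hi) < target_mean:
                break
            hi *= 2.0
        else:
            raise DegenerateArrayError("array mean cannot reach the target")
        f = float(brentq(lambda x: mean_sn(x) - target_mean, lo, hi, rtol=1e-15))
    sn = np.minimum(d / f + 1.0, cap)
    achieved = float(sn.mean())
    if abs(achieved - target_mean) / target_mean > rel_tol:
        raise DegenerateArrayError(
            f"normalization failed to reach mean {target_mean} (got {achieved})"
        )
    return ArraySignals(raw.array_id, "normalized", sn, raw_mean=float(v.mean()))


# ---------------------------------------------------------------------------
# error correction
# ---------------------------------------------------------------------------

def correct_errors(
    norm: ArraySignals,
    probeset: ProbeSet,
    window: int = 5,
    factor: float = 3.0,
    max_iter: int = 10,
    discard: bool = False,
) -> ArraySignals:
    """Correct noisy probe signals against the overlapping-probe structure.

    Along each allele's ordered probe track, a probe whose signal deviates
    from the rolling window median by more than ``factor`` (in ratio) is an
    outlier and is replaced by that median (or dropped to the window median
    regardless of direction; ``discard=True`` instead sets it to the scale
    minimum).  Passes repeat until a fixed point so the operation is
    idempotent.  Tracks shorter than the window are left untouched.
    """
    if window < 3:
        raise ConfigError(f"correction window must be >= 3 (got {window})")
    if norm.stage not in ("normalized", "corrected"):
        raise SignalInputError("error correction expects normalized-stage signals")
    v = norm.values.copy()
    log_factor = np.log(factor)
    for _ in range(max_iter):
        proposals: dict[int, list[float]] = {}
        for pids in probeset.allele_probes.values():
            if len(pids) < window:
                continue
            track = v[pids]
            med = median_filter(track, size=window, mode="nearest")
            with np.errstate(divide="ignore"):
                outlier = np.abs(np.log(track) - np.log(med)) > log_factor
            for pid, m in zip(pids[outlier], med[outlier]):
                proposals.setdefault(int(pid), []).append(float(m))
        if not proposals:
            break
        for pid, meds in proposals.items():
            v[pid] = SCALE_MIN if discard else float(np.median(meds))
    return ArraySignals(norm.array_id, "corrected", v, raw_mean=norm.raw_mean)


# ---------------------------------------------------------------------------
# thresholds & binarization
# ---------------------------------------------------------------------------

@dataclass
class ThresholdTable:
    """Per-probe positivity thresholds.

    ``values`` is parallel to the probe ids; NaN marks probes without a
    threshold (binarization falls back to the initial-fraction rule for
    those).  ``never_positive`` flags probes observed only at background in
    every knowledgebase template.
    """

    values: np.ndarray
    provenance: str  # 'initial-fraction' | 'empirical'
    never_positive: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": np.arange(self.values.size), "threshold": self.values}
        )


def compute_thresholds(
    templates: list[ArraySignals],
    probeset: ProbeSet,
    initial_fraction: float = DEFAULT_INITIAL_FRACTION,
    observed: list[ArraySignals] | None = None,
    default_max: float = SCALE_MAX,
    gap_factor: float = 4.0,
) -> ThresholdTable:
    """Derive per-probe thresholds.

    With no templates the rule is the initial one: ``initial_fraction`` of the
    maximal signal seen for the probe (across ``observed`` arrays if supplied,
    else the design-time scale maximum).  With templates the threshold is
    empirical: per probe, the signals are split at the largest log-gap into a
    low (negative) and a high (positive) mode and the threshold is the
    geometric midpoint of the gap.  Probes whose template signals form a
    single low mode are never-positive and get a threshold above all
    observations.
    """
    if not (0.0 < initial_fraction < 1.0):
        raise ConfigError(f"initial_fraction must be in (0,1), got {initial_fraction}")
    n = probeset.n_probes
    if not templates:
        if observed:
            maxima = np.max([a.values for a in observed], axis=0)
        else:
            maxima = np.full(n, default_max)
        return ThresholdTable(initial_fraction * maxima, "initial-fraction")

    mat = np.stack([t.values for t in templates])  # T x n
    srt = np.sort(mat, axis=0)
    log_srt = np.log(np.maximum(srt, 1e-12))
    thresholds = np.empty(n)
    never_positive = np.zeros(n, dtype=bool)
    if mat.shape[0] == 1:
        # a single template cannot exhibit two modes; fall back per probe
        thresholds[:] = initial_fraction * srt[-1]
        return ThresholdTable(thresholds, "empirical", never_positive)
    gaps = np.diff(log_srt, axis=0)
    split = np.argmax(gaps, axis=0)
    idx = np.arange(n)
    has_gap = gaps[split, idx] >= np.log(gap_factor)
    low = srt[split, idx]
    high = srt[split + 1, idx]
    thresholds[has_gap] = np.sqrt(low[has_gap] * high[has_gap])
    one_mode = ~has_gap
    low_mode = one_mode & (srt[-1] < SCALE_MEAN)
    high_mode = one_mode & ~low_mode
    thresholds[low_mode] = 2.0 * srt[-1, low_mode]  # above all observations
    never_positive[low_mode] = True
    thresholds[high_mode] = initial_fraction * srt[-1, high_mode]
    return ThresholdTable(thresholds, "empirical", never_positive)


def binarize(
    norm: ArraySignals,
    thresholds: ThresholdTable | None = None,
    initial_fraction: float = DEFAULT_INITIAL_FRACTION,
) -> np.ndarray:
    """Positive/negative call per probe (strict ``signal > threshold``).

    Probes lacking a threshold fall back to the initial-fraction rule
    evaluated against the array-wide maximum (the cold-start behaviour before
    any knowledgebase exists).
    """
    if norm.stage not in ("normalized", "corrected"):
        raise SignalInputError("binarization expects normalized or corrected signals")
    fallback = initial_fraction * float(norm.values.max())
    if thresholds is None:
        thr = np.full(norm.n_probes, fallback)
    else:
        thr = np.array(thresholds.values, dtype=float)
        if thr.size != norm.n_probes:
            raise SignalInputError("threshold table does not match the probe set size")
        missing = ~np.isfinite(thr)
        thr[missing] = fallback
    return norm.values > thr


def flag_uninformative_probes(
    arrays: list[ArraySignals],
    thresholds: ThresholdTable | None = None,
    initial_fraction: float = DEFAULT_INITIAL_FRACTION,
) -> np.ndarray:
    """Probes whose binarized state is identical across every array.

    Always-positive or always-negative probes carry no typing information;
    downstream negative-probe counting can exclude them.
    """
    if len(arrays) < 2:
        raise SignalInputError("uninformative-probe detection needs >= 2 arrays")
    calls = np.stack([binarize(a, thresholds, initial_fraction) for a in arrays])
    return np.all(calls == calls[0], axis=0)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    array_id: str
    raw_mean: float
    cohort_mean: float | None
    degraded: bool
    ratio: float | None = None


def qc_array(
    norm: ArraySignals,
    cohort_mean: float | None,
    min_ratio: float = DEFAULT_DEGRADED_RATIO,
) -> QCReport:
    """Flag globally attenuated (degraded) arrays.

    An array is degraded when its raw-scale mean falls below ``min_ratio`` of
    the cohort mean.  Degraded arrays are still typed but marked unreliable.
    With no cohort to compare against (single array), nothing is flagged.
    """
    raw_mean = norm.raw_mean if norm.raw_mean is not None else norm.mean_signal
    if cohort_mean is None:
        return QCReport(norm.array_id, raw_mean, None, False)
    ratio = raw_mean / cohort_mean
    return QCReport(norm.array_id, raw_mean, cohort_mean, ratio < min_ratio, ratio)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def array_correlation(a: ArraySignals, b: ArraySignals, log: bool = False) -> float:
    """Pearson correlation between two arrays' signal vectors.

    The default correlates the normalized signals directly (the scale the
    whole-array matching rule is defined on).  ``log=True`` correlates log
    signals instead; note that the normalization's minimum subtraction
    stretches the background tail on the log scale, which adds noise there.
    """
    x, y = a.values, b.values
    if x.size != y.size:
        raise SignalInputError("arrays cover different probe sets")
    if log:
        x, y = np.log(np.maximum(x, 1e-12)), np.log(np.maximum(y, 1e-12))
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(pearsonr(x, y).statistic)
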