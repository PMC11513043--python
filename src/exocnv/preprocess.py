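"""Per-kit coverage QC and normalisation shared by the depth-of-coverage callers.

Fixed pipeline order: GC-extreme target removal -> per-sample coverage QC ->
kit cohort-size gate -> 120 bp windowing -> GC/library-size correction ->
exclusion of systematically low windows -> square-root variance
stabilisation. No operation mixes samples across enrichment kits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

#: Targets with GC above this fraction amplify poorly and are removed.
GC_MAX = 0.80
#: A sample passes coverage QC iff at least this fraction of target bases
#: has depth of coverage >= MIN_DEPTH reads.
QC_MIN_FRACTION = 0.70
MIN_DEPTH = 10.0
#: Minimum control cohort per enrichment kit for calling.
MIN_KIT_COHORT = 30
WINDOW_SIZE = 120
#: A window is systematically low if >= LOW_SAMPLE_FRACTION of samples have
#: normalised coverage below LOW_COVERAGE.
LOW_COVERAGE = 0.30
LOW_SAMPLE_FRACTION = 0.90
GC_BIN_WIDTH = 0.05
GC_BIN_MIN_WINDOWS = 10


def remove_gc_extreme_targets(targets: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split targets into (kept, removed) by the strict GC > 0.80 rule."""
    if "gc" not in targets or targets["gc"].isna().any():
        raise ValueError("targets must carry a populated 'gc' column")
    removed = targets[targets["gc"] > GC_MAX]
    kept = targets[targets["gc"] <= GC_MAX]
    return kept, removed


def sample_coverage_qc(counts: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fraction of target bases at mean depth >= 10 reads.

    Per-target mean depth = count * read_length / target_length is not
    available without read lengths; counts here are taken as read counts and
    depth is approximated as count / (length / 150) i.e. assuming 150 bp
    reads fully on target. The fraction is base-weighted by target length.
    """
    if len(targets) == 0:
        raise ValueError("empty target set")
    lengths = (targets["end"] - targets["start"]).to_numpy(float)
    depth = counts.to_numpy(float) * 150.0 / lengths[:, None]
    frac = (lengths[:, None] * (depth >= MIN_DEPTH)).sum(axis=0) / lengths.sum()
    res = pd.DataFrame({
        "sample_id": counts.columns,
        "frac_targets_ge_10x": frac,
    })
    res["pass"] = res["frac_targets_ge_10x"] >= QC_MIN_FRACTION
    res["reason"] = np.where(res["pass"], "", "coverage_below_70pct_at_10x")
    return res


def kit_cohort_gate(samples: pd.DataFrame, min_cohort: int = MIN_KIT_COHORT) -> list[str]:
    """Kits with an available cohort below 30 samples are excluded from calling."""
    sizes = samples.groupby("kit_id")["sample_id"].nunique()
    return sorted(sizes.index[sizes >= min_cohort])


def windowize(targets: pd.DataFrame, window_size: int = WINDOW_SIZE) -> pd.DataFrame:
    """Tile each target with consecutive windows of <= window_size bp.

    Windows carry their parent target id; total window length equals total
    target length exactly.
    """
    rows = []
    for tid, t in zip(targets.index, targets.itertuples(index=False)):
        pos = t.start
        while pos < t.end:
            end = min(pos + window_size, t.end)
            rows.append((t.chrom, pos, end, t.gc, tid))
            pos = end
    win = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "target_id"])
    win.index = pd.Index(
        win["chrom"].astype(str) + ":" + win["start"].astype(str) + "-" + win["end"].astype(str),
        name="window_id")
    return win


def window_counts(counts: pd.DataFrame, targets: pd.DataFrame,
                  windows: pd.DataFrame) -> pd.DataFrame:
    """Apportion per-target counts to windows by length (uniform coverage
    within a target), yielding per-window expected read counts."""
    tlen = (targets["end"] - targets["start"]).astype(float)
    wlen = (windows["end"] - windows["start"]).astype(float)
    share = (wlen / tlen.reindex(windows["target_id"]).to_numpy()).to_numpy()
    mat = counts.reindex(windows["target_id"]).to_numpy(float) * share[:, None]
    return pd.DataFrame(mat, index=windows.index, columns=counts.columns)


def _gc_bins(gc: np.ndarray) -> np.ndarray:
    """Assign GC bins of width 0.05, merging bins with <10 windows into their
    lower neighbour so every bin supports a stable median."""
    edges = np.arange(0.0, 1.0 + GC_BIN_WIDTH, GC_BIN_WIDTH)
    raw = np.clip(np.digitize(gc, edges) - 1, 0, len(edges) - 2)
    # merge sparse bins leftward (then rightward for a sparse leftmost bin)
    ids = sorted(set(raw))
    remap = {}
    counts = {b: int((raw == b).sum()) for b in ids}
    merged: list[list[int]] = []
    for b in ids:
        if merged and counts[b] < GC_BIN_MIN_WINDOWS:
            merged[-1].append(b)
        elif merged and sum(counts[x] for x in merged[-1]) < GC_BIN_MIN_WINDOWS:
            merged[-1].append(b)
        else:
            merged.append([b])
    if len(merged) > 1 and sum(counts[x] for x in merged[0]) < GC_BIN_MIN_WINDOWS:
        merged[1] = merged[0] + merged[1]
        merged.pop(0)
    for gi, group in enumerate(merged):
        for b in group:
            remap[b] = gi
    return np.array([remap[b] for b in raw])


def gc_and_library_correct(counts: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Correct each sample for library size and GC bias.

    Library size is the per-sample median window coverage (robust to CNVs);
    within each sample, every window is divided by the median coverage of
    its GC bin so post-correction medians are flat in GC. Output is
    normalised coverage with sample-median ~= 1.
    """
    x = counts.to_numpy(float)
    med = np.median(x, axis=0)
    med[med == 0] = 1.0
    x = x / med
    bins = _gc_bins(windows["gc"].to_numpy())
    for b in np.unique(bins):
        m = bins == b
        bmed = np.median(x[m, :], axis=0)
        bmed[bmed <= 0] = 1.0
        x[m, :] = x[m, :] / bmed
    return pd.DataFrame(x, index=counts.index, columns=counts.columns)


def exclude_systematically_low(corrected: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude windows where >= 90% of samples have normalised coverage < 0.3.

    Input values are normalised coverage on a per-sample median-1 scale (the
    output of gc_and_library_correct), so 0.3 reads as 30% of a sample's
    typical window coverage; windows that low in nearly all samples are
    systematically poorly captured and carry no copy-number information.
    """
    frac_low = (corrected < LOW_COVERAGE).mean(axis=1)
    excluded_mask = frac_low >= LOW_SAMPLE_FRACTION
    return corrected[~excluded_mask], corrected[excluded_mask]


def variance_stabilize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Element-wise square root (delta method: stabilises Poisson-like
    variance to ~1/4 independent of the mean)."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative values cannot be variance-stabilised")
    return np.sqrt(matrix)


@dataclass
class PreprocessResult:
    """Outputs of the preprocessing pipeline for one enrichment kit."""

    windows: pd.DataFrame  # surviving windows (chrom, start, end, gc, target_id)
    matrix: pd.DataFrame  # sqrt-transformed normalised coverage, windows x samples
    qc: pd.DataFrame  # per-sample coverage QC report
    removed_targets: pd.DataFrame
    excluded_windows: pd.Index
    samples: pd.DataFrame  # metadata restricted to QC-passing samples


class CoveragePreprocessor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer running the fixed preprocessing pipeline.

    Parameters mirror the documented defaults; ``fit`` learns nothing beyond
    recording the surviving windows, and ``transform`` maps a raw per-target
    count matrix to the variance-stabilised window matrix.
    """

    def __init__(self, window_size: int = WINDOW_SIZE, qc_min_fraction: float = QC_MIN_FRACTION,
                 min_kit_cohort: int = MIN_KIT_COHORT, drop_failing_samples: bool = True):
        self.window_size = window_size
        self.qc_min_fraction = qc_min_fraction
        self.min_kit_cohort = min_kit_cohort
        self.drop_failing_samples = drop_failing_samples

    def fit(self, counts: pd.DataFrame, y=None, *, targets: pd.DataFrame,
            samples: pd.DataFrame | None = None):
        self.result_ = self._run(counts, targets, samples)
        self.windows_ = self.result_.windows
        return self

    def transform(self, counts: pd.DataFrame, *, targets: pd.DataFrame | None = None,
                  samples: pd.DataFrame | None = None) -> pd.DataFrame:
        if targets is None:
            return self.result_.matrix
        return self._run(counts, targets, samples).matrix

    def fit_transform_cohort(self, counts: pd.DataFrame, targets: pd.DataFrame,
                             samples: pd.DataFrame | None = None) -> PreprocessResult:
        self.fit(counts, targets=targets, samples=samples)
        return self.result_

    def _run(self, counts: pd.DataFrame, targets: pd.DataFrame,
             samples: pd.DataFrame | None) -> PreprocessResult:
        kept_targets, removed = remove_gc_extreme_targets(targets)
        counts = counts.loc[kept_targets.index]
        qc = sample_coverage_qc(counts, kept_targets)
        qc_pass = list(qc.loc[qc["pass"], "sample_id"])
        if self.drop_failing_samples:
            if not qc_pass:
                raise ValueError("no samples pass coverage QC")
            counts = counts[qc_pass]
        if len(counts.columns) < self.min_kit_cohort:
            warnings.warn(
                f"cohort of {len(counts.columns)} samples is below the minimum of "
                f"{self.min_kit_cohort}; calling on this kit is not recommended")
        windows = windowize(kept_targets, self.window_size)
        wc = window_counts(counts, kept_targets, windows)
        corrected = gc_and_library_correct(wc, windows)
        kept, excluded = exclude_systematically_low(corrected)
        matrix = variance_stabilize(kept)
        windows = windows.loc[matrix.index]
        if samples is not None:
            samples = samples[samples["sample_id"].isin(matrix.columns)].reset_index(drop=True)
        return PreprocessResult(windows, matrix, qc, removed, excluded.index, samples)
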