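"""Reference-matched beta-binomial CNV caller.

For each test sample an aggregate reference is built from the most
coverage-correlated samples in the batch. Per target, the test read count
given the combined test+reference total is modelled beta-binomially; the
expected test share under copy number c scales the diploid share by c/2.
Adjacent targets whose maximum-likelihood state agrees are merged into
candidate segments scored by a log10 Bayes factor of the best alternative
copy number against the diploid model; segments with BF > 15 become calls.
Sample-level QC requires test-vs-reference correlation >= 0.97. Observed/
expected read ratios map to copy-number bins (0, 1, 2, 3, 4, OTHER).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._genome import AUTOSOMES, ploidy

DEFAULT_BF_THRESHOLD = 15.0
QC_MIN_CORRELATION = 0.97
MAX_REFERENCE_MEMBERS = 10
#: stop greedy reference growth when the correlation gain drops below this
CORRELATION_GAIN_EPS = 1e-4
#: CN=0 modelled with a small residual share (mismaps, noise)
CN0_EFFECTIVE = 0.05

#: O/E ratio bins on diploid chromosomes; lower bound inclusive, upper
#: exclusive. Partition of [0, inf): 0, 1, 2, 3, 4, OTHER.
OE_BINS: list[tuple[float, float, object]] = [
    (0.00, 0.10, 0),
    (0.10, 0.75, 1),
    (0.75, 1.25, 2),
    (1.25, 1.75, 3),
    (1.75, 2.25, 4),
    (2.25, np.inf, "OTHER"),
]


def oe_ratio_to_cn(observed: float, expected: float):
    """Map an observed/expected read ratio to a copy-number label via the
    diploid-chromosome bin partition."""
    if expected <= 0:
        raise ValueError("expected reads must be > 0")
    ratio = observed / expected
    for lo, hi, label in OE_BINS:
        if lo <= ratio < hi:
            return label
    raise AssertionError("bins must partition [0, inf)")  # pragma: no cover


@dataclass
class ReferenceSet:
    test_sample_id: str
    member_sample_ids: list[str]
    aggregate: np.ndarray  # summed counts per target
    correlation: float


def select_reference(test_id: str, counts: pd.DataFrame,
                     max_members: int = MAX_REFERENCE_MEMBERS,
                     candidates: list[str] | None = None) -> ReferenceSet:
    """Greedy forward selection of the reference set.

    Candidates are ranked by Pearson correlation with the test profile;
    samples are added while the test-vs-aggregate correlation improves by
    more than CORRELATION_GAIN_EPS, up to max_members.
    """
    if candidates is None:
        candidates = [c for c in counts.columns if c != test_id]
    if not candidates:
        raise ValueError("need at least one candidate reference sample")
    x = counts[test_id].to_numpy(float)
    cand_mat = counts[candidates].to_numpy(float)
    base_corr = _pearson_many(x, cand_mat)
    order = np.argsort(-base_corr)
    members: list[str] = []
    agg = np.zeros_like(x)
    best = -np.inf
    for oi in order:
        trial = agg + cand_mat[:, oi]
        r = _pearson(x, trial)
        if r > best + CORRELATION_GAIN_EPS:
            agg = trial
            best = r
            members.append(candidates[oi])
            if len(members) >= max_members:
                break
        elif members:
            break
    return ReferenceSet(test_id, members, agg, float(best))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _pearson_many(a: np.ndarray, mat: np.ndarray) -> np.ndarray:
    a0 = a - a.mean()
    m0 = mat - mat.mean(axis=0)
    denom = a0.std() * mat.std(axis=0)
    denom[denom == 0] = np.inf
    return (a0[:, None] * m0).mean(axis=0) / denom


def exomedepth_qc(reference: ReferenceSet,
                  min_correlation: float = QC_MIN_CORRELATION) -> bool:
    """Pass iff the test-vs-aggregate-reference correlation is >= 0.97."""
    return reference.correlation >= min_correlation


def estimate_overdispersion(x: np.ndarray, n: np.ndarray, p0: float) -> float:
    """Method-of-moments beta-binomial intraclass correlation rho on
    presumed-diploid targets: Var(x/n) ~= p(1-p)/n * (1 + (n-1) rho)."""
    ok = n > 0
    z = x[ok] / n[ok]
    nbar = n[ok].mean()
    v = z.var()
    base = p0 * (1 - p0) / nbar
    if base <= 0:
        return 1e-6
    rho = (v / base - 1.0) / (nbar - 1.0)
    if not np.isfinite(rho) or rho <= 0:
        warnings.warn("overdispersion fit failed; falling back to binomial")
        return 1e-9
    return float(np.clip(rho, 1e-9, 0.5))


def _state_shares(p0: float, states: np.ndarray, baseline: float = 2.0) -> np.ndarray:
    """Expected test share under copy number c: the diploid odds scaled by
    c/baseline."""
    c_eff = np.maximum(states.astype(float), CN0_EFFECTIVE)
    scale = c_eff / baseline
    return (scale * p0) / (scale * p0 + (1 - p0))


def _bb_loglik(x: np.ndarray, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial log-pmf, (targets, states); binomial in the rho->0 limit."""
    if rho < 1e-8:
        return stats.binom.logpmf(x[:, None], n[:, None], p[None, :])
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return stats.betabinom.logpmf(x[:, None], n[:, None], a[None, :], b[None, :])


def beta_binomial_calls(test: pd.DataFrame | pd.Series, reference: ReferenceSet,
                        targets: pd.DataFrame, bf_threshold: float = DEFAULT_BF_THRESHOLD,
                        baseline_ploidy: np.ndarray | None = None) -> pd.DataFrame:
    """Segment and score one test sample against its aggregate reference.

    Per target the ML copy-number state (0..6) is taken; runs of agreeing
    non-baseline states within a chromosome merge into candidate segments.
    The segment state is re-chosen to maximise the summed segment
    likelihood, BF = log10 of its likelihood ratio against the baseline, and
    calls with BF > threshold are returned with O/E-ratio copy-number bins.
    """
    x = (test if isinstance(test, pd.Series) else test.iloc[:, 0]).to_numpy(float)
    r = reference.aggregate.astype(float)
    n = x + r
    tot_x, tot_r = x.sum(), r.sum()
    p0 = tot_x / (tot_x + tot_r)
    states = np.arange(0, 7)
    if baseline_ploidy is None:
        baseline_ploidy = np.full(len(x), 2.0)
    rho = estimate_overdispersion(x, n, p0)

    chrom = targets["chrom"].to_numpy()
    start = targets["start"].to_numpy()
    end = targets["end"].to_numpy()

    calls = []
    for base in np.unique(baseline_ploidy):
        if base == 0:
            continue
        sel = baseline_ploidy == base
        p_states = _state_shares(p0, states, baseline=float(base))
        ll = _bb_loglik(x[sel].astype(int), n[sel].astype(int), p_states, rho)
        base_ix = int(base)
        ml = np.argmax(ll, axis=1)
        idx = np.where(sel)[0]
        runs = _runs(ml, base_ix, chrom[idx])
        for a, b in runs:
            seg = slice(a, b)
            seg_ll = ll[seg].sum(axis=0)
            alt = [s for s in range(len(states)) if s != base_ix]
            best = max(alt, key=lambda s: seg_ll[s])
            bf = (seg_ll[best] - seg_ll[base_ix]) / np.log(10)
            if bf <= bf_threshold:
                continue
            obs = x[idx[seg]].sum()
            exp = (n[idx[seg]] * p_states[base_ix]).sum()
            if exp <= 0:
                continue
            ratio = obs / exp
            cn = oe_ratio_to_cn(obs, exp) if base == 2 else _nondiploid_cn(ratio, base)
            calls.append(dict(
                sample_id=reference.test_sample_id, chrom=chrom[idx[a]],
                start=int(start[idx[a]]), end=int(end[idx[b - 1]]),
                copy_number=cn, type="DEL" if ratio < 1 else "DUP",
                caller="exomedepth", quality=float(bf),
                n_windows=b - a, n_targets=b - a, oe_ratio=float(ratio),
            ))
    cols = ["sample_id", "chrom", "start", "end", "copy_number", "type",
            "caller", "quality", "n_windows", "n_targets", "oe_ratio"]
    return pd.DataFrame(calls, columns=cols)


def _nondiploid_cn(ratio: float, base: float):
    """Copy-number label on non-diploid baselines: round ratio x ploidy,
    OTHER beyond 4 copies (mirrors the diploid bin vocabulary)."""
    cn = int(round(ratio * base))
    return cn if cn <= 4 else "OTHER"


def _runs(ml: np.ndarray, base_ix: int, chrom: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of identical non-baseline ML states within a chromosome."""
    runs = []
    i, nt = 0, len(ml)
    while i < nt:
        if ml[i] == base_ix:
            i += 1
            continue
        j = i
        while j < nt and ml[j] == ml[i] and chrom[j] == chrom[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


class ExomeDepthCaller(BaseEstimator):
    """Reference-matched beta-binomial caller over a batch of samples.

    Autosomes use the whole batch as reference candidates; gonosomal targets
    restrict candidates to same-sex samples and sex-adjust the baseline.
    QC-failing samples (correlation < 0.97) yield no calls and are listed in
    ``qc_report_``.
    """

    def __init__(self, bf_threshold: float = DEFAULT_BF_THRESHOLD,
                 min_correlation: float = QC_MIN_CORRELATION,
                 max_reference_members: int = MAX_REFERENCE_MEMBERS):
        self.bf_threshold = bf_threshold
        self.min_correlation = min_correlation
        self.max_reference_members = max_reference_members

    def fit(self, counts: pd.DataFrame, y=None, *, targets: pd.DataFrame,
            samples: pd.DataFrame):
        self.counts_ = counts
        self.targets_ = targets
        self.samples_ = samples.reset_index(drop=True)
        auto = targets["chrom"].isin(AUTOSOMES).to_numpy()
        sex = samples.set_index("sample_id")["sex"]
        refs, qc = {}, []
        for sid in counts.columns:
            ref = select_reference(sid, counts[counts.columns].loc[auto],
                                   self.max_reference_members,
                                   [c for c in counts.columns if c != sid])
            refs[sid] = ref
            qc.append(dict(sample_id=sid, correlation=ref.correlation,
                           n_members=len(ref.member_sample_ids),
                           passed=exomedepth_qc(ref, self.min_correlation)))
        self.references_ = refs
        self.qc_report_ = pd.DataFrame(qc)
        self._sex = sex
        return self

    def predict(self) -> pd.DataFrame:
        out = []
        chrom = self.targets_["chrom"].to_numpy()
        start = self.targets_["start"].to_numpy()
        gono = ~self.targets_["chrom"].isin(AUTOSOMES).to_numpy()
        passed = set(self.qc_report_.loc[self.qc_report_["passed"], "sample_id"])
        for sid in self.counts_.columns:
            if sid not in passed:
                continue
            s_sex = self._sex.get(sid, "F")
            same_sex = [c for c in self.counts_.columns
                        if c != sid and self._sex.get(c, "F") == s_sex]
            members = [m for m in self.references_[sid].member_sample_ids
                       if m in same_sex] or same_sex[: self.max_reference_members]
            use = self.references_[sid].member_sample_ids
            baseline = np.array([ploidy(c, p, s_sex) for c, p in zip(chrom, start)], float)
            # autosomes + the expected test share are modelled against the
            # correlation-selected reference; gonosomes against a same-sex
            # reference as a separate calling problem with its own share
            # and overdispersion
            blocks = [(~gono, use)]
            if members:
                blocks.append((gono, members))
            for sel, mem in blocks:
                if not sel.any():
                    continue
                agg = self.counts_[mem].sum(axis=1).to_numpy(float)[sel]
                ref = ReferenceSet(sid, mem, agg, self.references_[sid].correlation)
                calls = beta_binomial_calls(self.counts_[sid][sel], ref,
                                            self.targets_[sel], self.bf_threshold,
                                            baseline[sel])
                out.append(calls)
        if not out:
            cols = ["sample_id", "chrom", "start", "end", "copy_number", "type",
                    "caller", "quality", "n_windows", "n_targets", "oe_ratio"]
            return pd.DataFrame(columns=cols)
        return pd.concat(out, ignore_index=True)

    def fit_predict(self, counts: pd.DataFrame, *, targets: pd.DataFrame,
                    samples: pd.DataFrame) -> pd.DataFrame:
        return self.fit(counts, targets=targets, samples=samples).predict()
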