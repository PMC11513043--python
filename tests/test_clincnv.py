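import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exocnv.clincnv import (cluster_samples, normalize_by_cluster, window_loglik,
                            segment_max_subarray, max_subarray_brute_force, _max_subarray,
                            sample_qc_regression, annotate_de_novo, robust_sigma,
                            ClinCnvCaller, CN_STATES, CN0_FLOOR)
from exocnv.simulate import SimConfig, CohortSimulator
from exocnv.preprocess import CoveragePreprocessor
from conftest import truth_window_span, found


# ---------------------------------------------------------------- clustering

def test_cluster_recovers_batches(cohort, preprocessed):
    cl = cluster_samples(preprocessed.matrix)
    merged = cl.merge(preprocessed.samples, on="sample_id")
    # best-match agreement between clusters and simulated processing batches
    tab = pd.crosstab(merged["cluster_id"], merged["batch"])
    agreement = sum(tab.max(axis=1)) / len(merged)
    assert agreement >= 0.95
    sizes = cl.groupby("cluster_id").size()
    assert (sizes >= 15).all()


def test_homogeneous_cohort_forms_single_cluster():
    cfg = SimConfig(targets_per_kit=600, samples_per_kit=40, batches_per_kit=1,
                    batch_effect_sd=0.0, gc_bias_strength=0.0, seed=4)
    cohort = CohortSimulator(cfg).run()
    kit = cohort.kits["KIT1"]
    pre = CoveragePreprocessor().fit_transform_cohort(kit.counts, kit.targets, cohort.samples)
    cl = cluster_samples(pre.matrix)
    assert cl["cluster_id"].nunique() == 1


def test_small_cohort_falls_back_to_single_cluster():
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.random((200, 14)), columns=[f"S{i}" for i in range(14)])
    with pytest.warns(UserWarning, match="single cluster"):
        cl = cluster_samples(mat)
    assert (cl["cluster_id"] == 0).all()


# ------------------------------------------------------------- normalisation

def test_cluster_medians_normalise_to_one(preprocessed, clincnv_fit):
    norm = clincnv_fit.normalized_
    cl = clincnv_fit.clusters_.set_index("sample_id")["cluster_id"]
    auto = ~preprocessed.windows["chrom"].isin(["X", "Y"]).to_numpy()
    for c in cl.unique():
        cols = [s for s in norm.columns if cl[s] == c]
        med = norm[cols].iloc[auto].median(axis=1)
        assert np.allclose(med, 1.0, atol=1e-9)


def test_sample_equal_to_cluster_median_maps_to_one():
    mat = pd.DataFrame(np.tile(np.arange(1.0, 6.0)[:, None], (1, 5)),
                       columns=[f"S{i}" for i in range(5)])
    assign = pd.DataFrame({"sample_id": mat.columns, "cluster_id": 0, "is_noise": False})
    out = normalize_by_cluster(mat, assign)
    assert np.allclose(out.to_numpy(), 1.0)


def test_heterozygous_deletion_sits_near_sqrt_half(cohort, preprocessed, clincnv_fit):
    norm = clincnv_fit.normalized_
    win = preprocessed.windows
    hits = 0
    for _, ev in cohort.truth.iterrows():
        if (ev["copy_number"] != 1 or ev["chrom"] in ("X", "Y") or ev["common_locus"]
                or ev["n_targets"] < 4 or ev["sample_id"] not in norm.columns):
            continue
        m = ((win["chrom"] == ev["chrom"]) & (win["start"] >= ev["start"])
             & (win["start"] < ev["end"])).to_numpy()
        if m.sum() < 4:
            continue
        val = norm.loc[m, ev["sample_id"]].mean()
        assert val == pytest.approx(np.sqrt(0.5), abs=0.07)
        hits += 1
    assert hits >= 2


# ------------------------------------------------------------ log-likelihood

def test_loglik_matches_direct_density_evaluation():
    rng = np.random.default_rng(1)
    x = pd.DataFrame(rng.normal(1, 0.1, (50, 4)))
    baseline = np.full(50, 2.0)
    sigma = rng.uniform(0.03, 0.2, 50)
    ll = window_loglik(x, baseline, sigma)
    c_eff = np.maximum(CN_STATES.astype(float), CN0_FLOOR)
    for s, c in enumerate(c_eff):
        expect = stats.norm.logpdf(x.to_numpy(), np.sqrt(c / 2.0), sigma[:, None])
        assert np.allclose(ll[:, :, s], expect, atol=1e-9)


def test_loglik_argmax_picks_nearest_state():
    x = pd.DataFrame([[1.0], [np.sqrt(0.5)]])
    ll = window_loglik(x, np.array([2.0, 2.0]), np.array([0.05, 0.05]))
    assert ll[0, 0].argmax() == 2
    assert ll[1, 0].argmax() == 1


def test_robust_sigma_floor_on_degenerate_input():
    mat = pd.DataFrame(np.ones((5, 20)))
    assert (robust_sigma(mat) > 0).all()


# -------------------------------------------------------------- segmentation

def brute_force_segmentation(ll, baseline_state, min_loglik):
    """Independent oracle: exhaustive search over every (state, i, j)
    contiguous segment with the same iterative masking and tie rules
    (highest sum, then longest, then leftmost, then smallest state)."""
    nw, nstates = ll.shape
    scores = ll - ll[:, [baseline_state]]
    masked = np.zeros(nw, bool)
    calls = []
    while True:
        best = None
        for s in range(nstates):
            if s == baseline_state:
                continue
            for i in range(nw):
                for j in range(i + 1, nw + 1):
                    if masked[i:j].any():
                        continue
                    tot = float(scores[i:j, s].sum())
                    cand = (tot, i, j, s)
                    if best is None or _oracle_better(cand, best):
                        best = cand
        if best is None or best[0] < min_loglik:
            break
        tot, i, j, s = best
        calls.append((s, i, j, tot))
        masked[i:j] = True
    return calls


def _oracle_better(a, b):
    if not np.isclose(a[0], b[0]):
        return a[0] > b[0]
    la, lb = a[2] - a[1], b[2] - b[1]
    if la != lb:
        return la > lb
    if a[1] != b[1]:
        return a[1] < b[1]
    return a[3] < b[3]


def test_segmentation_equivalent_to_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        nw = int(rng.integers(2, 21))
        ll = rng.normal(0, 3, (nw, 7))
        thr = float(rng.uniform(1, 8))
        fast = segment_max_subarray(ll, 2, thr)
        slow = brute_force_segmentation(ll, 2, thr)
        assert len(fast) == len(slow)
        for f, o in zip(fast, slow):
            assert f[:3] == (CN_STATES[o[0]], o[1], o[2])
            assert f[3] == pytest.approx(o[3], abs=1e-6)


def test_kadane_matches_exhaustive_max_subarray():
    rng = np.random.default_rng(7)
    for _ in range(300):
        arr = rng.normal(0, 1, int(rng.integers(1, 30)))
        fast, slow = _max_subarray(arr), max_subarray_brute_force(arr)
        assert fast[1:] == slow[1:]
        assert fast[0] == pytest.approx(slow[0], abs=1e-9)


def test_all_negative_scores_produce_no_calls():
    ll = np.zeros((3, 7))
    ll[:, :] = -5.0
    ll[:, 2] = 0.0  # baseline always preferred
    assert segment_max_subarray(ll, 2, 20.0) == []


def test_raising_threshold_never_adds_calls():
    rng = np.random.default_rng(5)
    for _ in range(50):
        ll = rng.normal(0, 4, (int(rng.integers(5, 40)), 7))
        prev = None
        for thr in (5.0, 10.0, 20.0, 40.0):
            calls = set(segment_max_subarray(ll, 2, thr))
            if prev is not None:
                assert calls.issubset(prev)
            prev = calls


def test_spiked_deletion_recovered_with_tight_boundaries():
    rng = np.random.default_rng(9)
    nw, ns = 300, 50
    sigma = 0.05
    mat = pd.DataFrame(rng.normal(1.0, sigma, (nw, ns)),
                       columns=[f"S{i}" for i in range(ns)])
    mat.iloc[100:110, 0] = rng.normal(np.sqrt(0.5), sigma, 10)
    windows = pd.DataFrame({"chrom": "1", "start": np.arange(nw) * 1000,
                            "end": np.arange(nw) * 1000 + 120,
                            "target_id": [f"t{i}" for i in range(nw)]})
    samples = pd.DataFrame({"sample_id": mat.columns, "sex": "F",
                            "family_id": "F0", "relationship": "proband"})
    caller = ClinCnvCaller()
    caller.fit(mat, windows=windows, samples=samples)
    calls = caller.predict()
    mine = calls[calls["sample_id"] == "S0"]
    assert len(mine) == 1
    call = mine.iloc[0]
    assert call["copy_number"] == 1 and call["type"] == "DEL"
    assert abs(call["start"] - 100_000) <= 1000
    assert abs(call["end"] - (109_000 + 120)) <= 1000


# ---------------------------------------------------------------- sample QC

def _qc_samples(n):
    return pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)],
                         "library_size": np.linspace(80, 200, n),
                         "kit_id": "K", "ancestry_label": ["EUR", "AFR"] * (n // 2)})


def _calls_for(sample_counts):
    rows = []
    for sid, per_chrom in sample_counts.items():
        for chrom, k in per_chrom.items():
            for i in range(k):
                rows.append(dict(sample_id=sid, chrom=chrom, start=i * 1000,
                                 end=i * 1000 + 500, type="DEL"))
    return pd.DataFrame(rows)


def test_identical_call_counts_all_pass():
    samples = _qc_samples(40)
    calls = _calls_for({s: {"1": 2, "2": 2} for s in samples["sample_id"]})
    res = sample_qc_regression(calls, samples)
    assert res["pass"].all()


def test_extreme_outlier_fails_qc():
    samples = _qc_samples(40)
    counts = {s: {"1": 2, "2": 2, "3": 1} for s in samples["sample_id"]}
    counts["S0"] = {c: 50 for c in map(str, range(1, 23))}
    res = sample_qc_regression(_calls_for(counts), samples).set_index("sample_id")
    assert not res.loc["S0", "pass"]
    assert res.drop("S0")["pass"].all()


def test_single_fragmented_chromosome_does_not_fail_sample():
    samples = _qc_samples(40)
    counts = {s: {"1": 2, "2": 2, "3": 1} for s in samples["sample_id"]}
    counts["S0"] = dict(counts["S0"], **{"7": 60})  # one shattered chromosome
    res = sample_qc_regression(_calls_for(counts), samples).set_index("sample_id")
    assert res.loc["S0", "pass"]


# ------------------------------------------------------------------ de novo

@pytest.fixture(scope="module")
def trio_run():
    cfg = SimConfig(targets_per_kit=1200, samples_per_kit=90, fraction_trios=1.0,
                    cnv_rate_per_sample=2.0, seed=17)
    cohort = CohortSimulator(cfg).run()
    kit = cohort.kits["KIT1"]
    pre = CoveragePreprocessor().fit_transform_cohort(kit.counts, kit.targets, cohort.samples)
    caller = ClinCnvCaller()
    caller.fit(pre.matrix, windows=pre.windows, samples=pre.samples)
    calls = caller.predict()
    flagged = annotate_de_novo(calls, pre.samples, caller.normalized_, pre.windows)
    return cohort, pre, flagged


def test_de_novo_flags_match_simulated_inheritance(trio_run):
    cohort, pre, calls = trio_run
    truth = cohort.truth
    checked_dn = checked_inh = 0
    probands = set(cohort.samples.loc[cohort.samples["relationship"] == "proband",
                                      "sample_id"])
    trio_probands = {p for p in probands
                     if (cohort.samples["family_id"]
                         == cohort.samples.set_index("sample_id").loc[p, "family_id"]).sum() == 3}
    for _, ev in truth.iterrows():
        if (ev["sample_id"] not in trio_probands or ev["common_locus"]
                or ev["chrom"] in ("X", "Y")
                or truth_window_span(ev, pre.windows) < 4):
            continue
        m = calls[(calls["sample_id"] == ev["sample_id"]) & (calls["chrom"] == ev["chrom"])
                  & (calls["start"] < ev["end"]) & (ev["start"] < calls["end"])]
        if m.empty:
            continue
        if ev["de_novo"]:
            assert (m["de_novo"] == "de_novo").any()
            checked_dn += 1
        else:
            assert (m["de_novo"] == "inherited").any()
            checked_inh += 1
    assert checked_dn >= 2 and checked_inh >= 2


def test_missing_parent_gives_unknown_flag():
    calls = pd.DataFrame([dict(sample_id="P1", chrom="1", start=0, end=1000,
                               copy_number=1, type="DEL")])
    samples = pd.DataFrame([
        dict(sample_id="P1", family_id="F1", relationship="proband", sex="F"),
        dict(sample_id="M1", family_id="F1", relationship="mother", sex="F"),
    ])
    norm = pd.DataFrame(np.ones((3, 2)), columns=["P1", "M1"])
    windows = pd.DataFrame({"chrom": ["1"] * 3, "start": [0, 200, 400],
                            "end": [120, 320, 520]})
    out = annotate_de_novo(calls, samples, norm, windows)
    assert out["de_novo"].iloc[0] == "unknown"


# -------------------------------------------------------------- stability

def test_half_cohort_runs_agree_on_multiwindow_events():
    # splitting must happen within one homogeneous cluster: a 60-sample
    # single-batch cohort halves into two 30-sample runs
    cfg = SimConfig(targets_per_kit=1500, samples_per_kit=60, batches_per_kit=1,
                    cnv_rate_per_sample=2.0, seed=23)
    cohort = CohortSimulator(cfg).run()
    kit = cohort.kits["KIT1"]
    pre = CoveragePreprocessor().fit_transform_cohort(kit.counts, kit.targets, cohort.samples)
    full = ClinCnvCaller().fit_predict(pre.matrix, windows=pre.windows, samples=pre.samples)
    full_found = [ev for _, ev in cohort.truth.iterrows()
                  if not ev["common_locus"] and ev["chrom"] not in ("X", "Y")
                  and truth_window_span(ev, pre.windows) >= 3 and found(full, ev)]
    assert len(full_found) >= 5
    cols = list(pre.matrix.columns)
    agree = total = 0
    for half in (cols[::2], cols[1::2]):
        samples = pre.samples[pre.samples["sample_id"].isin(half)]
        caller = ClinCnvCaller()
        caller.fit(pre.matrix[half], windows=pre.windows, samples=samples)
        calls = caller.predict()
        for ev in full_found:
            if ev["sample_id"] in half:
                total += 1
                agree += found(calls, ev)
    assert total >= 3
    assert agree / total >= 0.8
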