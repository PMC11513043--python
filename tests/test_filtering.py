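import numpy as np
import pandas as pd
import pytest

from exocnv.filtering import (FilterConfig, frequency_filter, gene_list_filter, classify,
                              classify_calls, double_hit_match, apply_ern_strategy,
                              effective_copy_number, CLASSES)


def _call(sample="S1", chrom="1", start=1000, end=2000, cn=1, cnv_type="DEL",
          caller="clincnv", quality=50.0, n_targets=3, **extra):
    return dict(sample_id=sample, chrom=chrom, start=start, end=end, copy_number=cn,
                type=cnv_type, caller=caller, quality=quality, n_targets=n_targets,
                n_windows=n_targets, **extra)


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end",
                                       "ern_lists", "inheritance", "pli",
                                       "ddd_hi_score", "validity_score"])


GENES = _genes([
    ("G1", "GENE1", "1", 500, 3000, "RND;ITHACA", "AD", 0.9, 20.0, 4),
    ("G2", "GENE2", "1", 10_000, 20_000, "RND", "AR", 0.5, 50.0, 2),
    ("G3", "GENE3", "2", 500, 3000, "EURO-NMD", "AD", 0.05, 95.0, 3),
    ("G4", "GENE4", "2", 10_000, 20_000, "EURO-NMD", "AR", 0.5, 50.0, 3),
])


# ------------------------------------------------------------ frequency filter

def test_frequency_filter_threshold_is_strictly_above_one_percent():
    base = [_call(sample=f"S{i}", start=1000, end=2000) for i in range(3)]
    calls = pd.DataFrame(base)
    kept, removed = frequency_filter(calls, 200)  # 3/200 = 1.5% > 1%
    assert len(removed) == 3 and kept.empty
    kept, removed = frequency_filter(calls.iloc[:2], 200)  # 2/200 = 1.0%, not more
    assert len(kept) == 2 and removed.empty


def test_frequency_filter_is_type_specific():
    rows = [_call(sample=f"S{i}", cnv_type="DUP", cn=3) for i in range(5)]
    rows.append(_call(sample="S99", cnv_type="DEL", cn=1))
    kept, removed = frequency_filter(pd.DataFrame(rows), 100)
    assert set(removed["type"]) == {"DUP"}
    assert list(kept["sample_id"]) == ["S99"]


def test_frequency_filter_counts_nested_fragments_once_per_individual():
    rows = [_call(sample=f"S{i}", start=1000, end=9000) for i in range(3)]
    # a one-target fragment of the same locus from another caller
    rows.append(_call(sample="S0", start=4000, end=4500, caller="conifer"))
    kept, removed = frequency_filter(pd.DataFrame(rows), 100)
    assert kept.empty  # the fragment's region is carried by 3 individuals


def test_frequency_filter_sample_order_invariant():
    rng = np.random.default_rng(0)
    rows = [_call(sample=f"S{i}", start=int(s), end=int(s) + 1000)
            for i, s in enumerate(rng.integers(0, 50_000, 40))]
    rows += [_call(sample=f"C{i}", start=100_000, end=101_000) for i in range(5)]
    calls = pd.DataFrame(rows)
    kept1, _ = frequency_filter(calls, 100)
    shuffled = calls.sample(frac=1.0, random_state=1)
    kept2, _ = frequency_filter(shuffled, 100)
    key = lambda df: sorted(map(tuple, df[["sample_id", "start", "end"]].to_numpy()))
    assert key(kept1) == key(kept2)


# -------------------------------------------------------------- gene-list filter

def test_gene_list_filter_one_bp_overlap_suffices():
    calls = pd.DataFrame([
        _call(start=2999, end=8000),      # 1 bp overlap with GENE1
        _call(start=4000, end=9000),      # gene desert
        _call(start=30_000, end=640_000, cnv_type="DUP", cn=3),  # >500kb, no gene
    ])
    kept = gene_list_filter(calls, GENES, "RND")
    assert len(kept) == 2
    assert 4000 not in kept["start"].values


def test_chry_keeps_only_long_calls():
    calls = pd.DataFrame([
        _call(chrom="Y", start=1000, end=5000),
        _call(chrom="Y", start=1000, end=600_000),
    ])
    kept = gene_list_filter(calls, GENES, "RND")
    assert list(kept["end"]) == [600_000]


# ---------------------------------------------------------------- classification

def test_classification_examples():
    assert classify(_call(start=0, end=600_000, cn=1), "F", GENES) == "LONG"
    assert classify(_call(start=700, end=1000, cn=0), "F", GENES) == "HOM_DEL"
    assert classify(_call(chrom="X", cn=3, cnv_type="DUP"), "F", GENES) == "GONOSOMAL"
    assert classify(_call(cn=4, cnv_type="DUP"), "F", GENES) == "HIGH_CN"
    assert classify(_call(cn="OTHER", cnv_type="DUP"), "F", GENES) == "HIGH_CN"
    # CN1 in an AD gene
    assert classify(_call(start=700, end=1000, cn=1), "F", GENES) == "HET_AD"
    # CN1 in an AR-only gene with no SNV partner: no class
    assert classify(_call(start=11_000, end=12_000, cn=1), "F", GENES) is None
    # neutral autosomal calls are unclassifiable
    assert classify(_call(cn=2, cnv_type="DEL"), "F", GENES) is None


def test_precedence_long_beats_everything():
    call = _call(chrom="X", start=0, end=700_000, cn=0)
    assert classify(call, "F", GENES) == "LONG"


def test_conifer_calls_class_as_single_copy_changes():
    assert effective_copy_number(_call(cn=pd.NA, cnv_type="DEL", caller="conifer")) == 1
    assert effective_copy_number(_call(cn=pd.NA, cnv_type="DUP", caller="conifer")) == 3
    assert classify(_call(cn=pd.NA, cnv_type="DEL", caller="conifer",
                          start=700, end=1000), "F", GENES) == "HET_AD"


def test_classified_calls_have_exactly_one_label(cohort):
    rng = np.random.default_rng(1)
    rows = [_call(sample=f"S{i}", chrom="1", start=int(s), end=int(s) + int(l),
                  cn=int(c), cnv_type="DEL" if c < 2 else "DUP")
            for i, (s, l, c) in enumerate(zip(rng.integers(0, 10**6, 50),
                                              rng.integers(200, 10**6, 50),
                                              rng.choice([0, 1, 3, 4], 50)))]
    samples = pd.DataFrame({"sample_id": [f"S{i}" for i in range(50)], "sex": "F"})
    out = classify_calls(pd.DataFrame(rows), samples, GENES)
    assert out["cnv_class"].isin(CLASSES).all()
    assert out["cnv_class"].notna().all()


# ------------------------------------------------------------------- double hit

SNVS = pd.DataFrame([
    ("S1", "GENE2", "1", 15_000, "het", True, ""),
    ("S1", "GENE1", "1", 1500, "het", True, ""),     # AD gene: no pair
    ("S2", "GENE2", "1", 15_000, "het", False, ""),  # not pathogenic
], columns=["sample_id", "gene", "chrom", "pos", "zygosity", "pathogenic", "note"])


def test_double_hit_requires_het_del_in_biallelic_gene():
    calls = pd.DataFrame([
        _call(sample="S1", start=11_000, end=12_000),          # AR gene, het DEL
        _call(sample="S1", start=700, end=1000),               # AD gene
        _call(sample="S1", start=11_000, end=12_000, cn=0),    # homozygous
        _call(sample="S2", start=11_000, end=12_000),          # SNV not pathogenic
    ])
    pairs = double_hit_match(calls, SNVS, GENES)
    assert len(pairs) == 1
    assert pairs.iloc[0]["gene"] == "GENE2" and pairs.iloc[0]["sample_id"] == "S1"


def test_recovers_simulator_constructed_pairs(cohort):
    truth = cohort.truth
    calls = pd.DataFrame([
        _call(sample=ev["sample_id"], chrom=ev["chrom"], start=ev["start"],
              end=ev["end"], cn=int(ev["copy_number"]),
              cnv_type="DEL" if ev["copy_number"] < 2 else "DUP")
        for _, ev in truth.iterrows()])
    pairs = double_hit_match(calls, cohort.snvs, cohort.genes)
    got = set(zip(pairs["sample_id"], pairs["gene"]))
    expect = set(zip(cohort.pairs["sample_id"], cohort.pairs["gene"]))
    assert got == expect
    assert len(expect) > 0


# ---------------------------------------------------------------- ERN strategies

def _classified(rows):
    df = pd.DataFrame(rows)
    return df


def test_euro_nmd_discards_deletion_tolerant_genes():
    calls = _classified([
        dict(_call(chrom="2", start=700, end=1000, cn=1), cnv_class="HET_AD"),
        dict(_call(chrom="2", start=11_000, end=12_000, cn=1), cnv_class="DOUBLE_HIT"),
    ])
    out = apply_ern_strategy(calls, "EURO-NMD", GENES)
    # GENE3 has HI score 95 (>90) and pLI 0.05 (<0.1): discarded
    assert out.iloc[0]["decision"] == "discard"
    assert "tolerant" in out.iloc[0]["reason"]


def test_euro_nmd_discards_low_loglik_and_ar_only():
    calls = _classified([
        dict(_call(chrom="2", start=700, end=1000, cn=3, cnv_type="DUP", quality=25.0),
             cnv_class="HET_AD"),
        dict(_call(chrom="2", start=11_000, end=12_000, cn=3, cnv_type="DUP",
                   quality=80.0), cnv_class="HET_AD"),
    ])
    out = apply_ern_strategy(calls, "EURO-NMD", GENES)
    assert out.iloc[0]["decision"] == "discard"      # loglik 25 < 30
    assert out.iloc[1]["decision"] == "discard"      # AR-only gene


def test_genturis_tiers():
    calls = _classified([
        dict(_call(sample="SA", start=1000, end=2000, quality=5.0), cnv_class="HET_AD"),
        dict(_call(sample="SA", start=1000, end=2000, quality=5.0, caller="exomedepth"),
             cnv_class="HET_AD"),
        dict(_call(sample="SB", start=5000, end=6000, quality=25.0), cnv_class="HET_AD"),
        dict(_call(sample="SC", start=8000, end=9000, quality=10.0), cnv_class="HET_AD"),
    ])
    out = apply_ern_strategy(calls, "GENTURIS", GENES)
    assert list(out["decision"]) == ["priority", "priority", "keep", "discard"]


def test_ithaca_length_rules_and_de_novo_exception():
    calls = _classified([
        dict(_call(start=1000, end=9000, cn=1), cnv_class="HET_AD", de_novo="unknown"),
        dict(_call(start=1000, end=9000, cn=1), cnv_class="HET_AD", de_novo="de_novo"),
        dict(_call(start=1000, end=9000, cn=0), cnv_class="HOM_DEL", de_novo="unknown"),
        dict(_call(start=1000, end=16_000, cn=3, cnv_type="DUP"), cnv_class="HET_AD",
             de_novo="unknown"),
        dict(_call(start=0, end=250_000, cn=3, cnv_type="DUP"), cnv_class="HET_AD",
             de_novo="unknown"),
    ])
    out = apply_ern_strategy(calls, "ITHACA", GENES)
    assert out.iloc[0]["decision"] == "discard"   # DEL < 10 kb
    assert out.iloc[1]["decision"] != "discard"   # de novo exception
    assert out.iloc[2]["decision"] != "discard"   # homozygous-deletion exception
    assert out.iloc[3]["decision"] == "discard"   # DUP < 20 kb
    assert out.iloc[4]["decision"] == "priority"  # >=200 kb regardless of genes


def test_ithaca_discards_flagged_calls_and_prioritises_valid_genes():
    calls = _classified([
        dict(_call(start=1000, end=15_000, cn=1), cnv_class="HET_AD",
             blacklist=True),
        dict(_call(start=1000, end=15_000, cn=1), cnv_class="HET_AD", benign=True),
        dict(_call(start=700, end=15_000, cn=1), cnv_class="HET_AD"),
    ])
    out = apply_ern_strategy(calls, "ITHACA", GENES)
    assert out.iloc[0]["decision"] == "discard"
    assert out.iloc[1]["decision"] == "discard"
    assert out.iloc[2]["decision"] == "priority"  # GENE1 validity 4 >= 3


def test_rnd_rules():
    calls = _classified([
        dict(_call(sample="SA", quality=25.0), cnv_class="HET_AD"),
        dict(_call(sample="SB", quality=250.0), cnv_class="HET_AD"),
        dict(_call(sample="SC", caller="exomedepth", quality=40.0, n_targets=2),
             cnv_class="HET_AD"),
        dict(_call(sample="SD", caller="exomedepth", quality=25.0, n_targets=5),
             cnv_class="HET_AD"),
        dict(_call(sample="SE", caller="conifer", cn=pd.NA, quality=2.0),
             cnv_class="HET_AD"),
    ])
    out = apply_ern_strategy(calls, "RND", GENES)
    assert out.iloc[0]["decision"] == "discard"   # loglik < 30
    assert out.iloc[1]["decision"] == "priority"  # loglik > 200
    assert out.iloc[2]["decision"] == "discard"   # <3 targets, unsupported
    assert out.iloc[3]["decision"] == "discard"   # BF < 30, unsupported
    assert out.iloc[4]["decision"] == "keep"      # all SVD-caller calls analysed


def test_rnd_keeps_supported_exomedepth_call():
    calls = _classified([
        dict(_call(sample="SA", start=1000, end=2000, caller="exomedepth",
                   quality=20.0, n_targets=2), cnv_class="HET_AD"),
        dict(_call(sample="SA", start=1000, end=2000, caller="clincnv",
                   quality=100.0), cnv_class="HET_AD"),
    ])
    out = apply_ern_strategy(calls, "RND", GENES)
    assert out.iloc[0]["decision"] == "keep"  # overlapped by another caller


def test_unknown_ern_raises():
    with pytest.raises(ValueError):
        apply_ern_strategy(pd.DataFrame([_call()]).assign(cnv_class="HET_AD"),
                           "NOPE", GENES)
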