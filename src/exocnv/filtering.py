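"""Cohort-level triage of pooled CNV calls.

Stages: cohort frequency filter (calls carried by >1% of individuals are too
common to explain a rare disease), restriction to ERN gene-panel overlaps
(long calls >500 kb survive regardless; on chrY only long calls survive),
categorisation into six non-redundant interpretation classes, SNV/CNV
compound-heterozygote double-hit matching, and the four ERN-specific
prioritisation rule sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import reciprocal_overlap

CLASSES = ["LONG", "GONOSOMAL", "HOM_DEL", "HIGH_CN", "DOUBLE_HIT", "HET_AD"]


@dataclass
class ErnEuroNmdConfig:
    hi_discard_above: float = 90.0
    pli_discard_below: float = 0.1
    min_loglik: float = 30.0


@dataclass
class ErnGenturisConfig:
    min_loglik: float = 20.0
    min_bf: float = 15.0


@dataclass
class ErnIthacaConfig:
    min_del_bp: int = 10_000
    min_dup_bp: int = 20_000
    keep_regardless_bp: int = 200_000
    min_validity: int = 3


@dataclass
class ErnRndConfig:
    loglik_discard_below: float = 30.0
    loglik_priority_above: float = 200.0
    min_targets: int = 3
    bf_discard_below: float = 30.0


@dataclass
class FilterConfig:
    """Every numeric triage threshold in one place (defaults as published)."""

    freq_threshold: float = 0.01
    long_cnv_bp: int = 500_000
    conifer_z: float = 1.75
    clincnv_loglik: float = 20.0
    exomedepth_bf: float = 15.0
    reciprocal_overlap: float = 0.5
    euro_nmd: ErnEuroNmdConfig = field(default_factory=ErnEuroNmdConfig)
    genturis: ErnGenturisConfig = field(default_factory=ErnGenturisConfig)
    ithaca: ErnIthacaConfig = field(default_factory=ErnIthacaConfig)
    rnd: ErnRndConfig = field(default_factory=ErnRndConfig)


# ----------------------------------------------------------- frequency filter

def frequency_filter(calls: pd.DataFrame, n_individuals: int,
                     config: FilterConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove calls seen (same type, >=50% reciprocal overlap) in more than
    1% of individuals. Caller-agnostic: carriers are counted as distinct
    individuals across all callers' pooled calls."""
    config = config or FilterConfig()
    if calls.empty:
        return calls, calls
    removed = np.zeros(len(calls), bool)
    limit = config.freq_threshold * n_individuals
    for (_, _), grp in calls.groupby(["type", "chrom"], sort=False):
        idx = grp.index.to_numpy()
        s = grp["start"].to_numpy(float)
        e = grp["end"].to_numpy(float)
        sids = grp["sample_id"].to_numpy()
        for i in range(len(idx)):
            # a call is common when its own region carries same-type calls in
            # too many individuals: count carriers whose call covers at least
            # half of the candidate (callers fragment the same locus with
            # discordant boundaries, so a candidate nested in another
            # individual's call still marks that individual as a carrier,
            # while a tiny unrelated call inside a large candidate does not
            # make the candidate's region common)
            inter = np.minimum(e[i], e) - np.maximum(s[i], s)
            frac = np.maximum(inter, 0) / (e[i] - s[i])
            carriers = len(set(sids[frac >= config.reciprocal_overlap]))
            if carriers > limit:
                removed[calls.index.get_loc(idx[i])] = True
    return calls[~removed], calls[removed]


# ------------------------------------------------------------ gene-list tools

def _overlapping_genes(call, genes: pd.DataFrame) -> pd.DataFrame:
    m = ((genes["chrom"] == call["chrom"]) & (genes["start"] < call["end"])
         & (call["start"] < genes["end"]))
    return genes[m]


def _ern_genes(genes: pd.DataFrame, ern: str) -> pd.DataFrame:
    in_ern = genes["ern_lists"].fillna("").str.split(";").apply(lambda L: ern in L)
    return genes[in_ern]


def gene_list_filter(calls: pd.DataFrame, genes: pd.DataFrame, ern: str,
                     config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep calls overlapping >=1 bp of an ERN-listed gene; long calls
    (>500 kb) are kept regardless; on chrY only long calls survive."""
    config = config or FilterConfig()
    panel = _ern_genes(genes, ern)
    keep = []
    for _, call in calls.iterrows():
        is_long = (call["end"] - call["start"]) > config.long_cnv_bp
        if call["chrom"] == "Y":
            keep.append(is_long)
            continue
        keep.append(is_long or len(_overlapping_genes(call, panel)) > 0)
    return calls[np.array(keep, bool)]


# ------------------------------------------------------------- classification

def effective_copy_number(call) -> object:
    """Copy number used for classing; callers without one (SVD residual
    calls) contribute DEL->1, DUP->3."""
    cn = call.get("copy_number")
    if cn is None or (isinstance(cn, float) and np.isnan(cn)) or cn is pd.NA:
        return 1 if call["type"] == "DEL" else 3
    return cn


def classify(call, sex: str, genes: pd.DataFrame, snvs: pd.DataFrame | None = None,
             config: FilterConfig | None = None) -> str | None:
    """Assign one of the six non-redundant interpretation classes.

    Precedence LONG > GONOSOMAL > HOM_DEL > HIGH_CN > DOUBLE_HIT > HET_AD:
    the broadest evidence class wins. Returns None for calls in no class
    (rejected upstream of interpretation).
    """
    config = config or FilterConfig()
    cn = effective_copy_number(call)
    length = call["end"] - call["start"]
    if length > config.long_cnv_bp:
        return "LONG"
    if call["chrom"] in ("X", "Y"):
        return "GONOSOMAL"
    if cn == 0:
        return "HOM_DEL"
    if cn != "OTHER" and cn >= 4 or cn == "OTHER":
        return "HIGH_CN"
    if snvs is not None and cn == 1 and _double_hit_partner(call, snvs, genes):
        return "DOUBLE_HIT"
    if cn in (1, 3):
        overlapped = _overlapping_genes(call, genes)
        if (overlapped["inheritance"] == "AD").any():
            return "HET_AD"
    return None


def classify_calls(calls: pd.DataFrame, samples: pd.DataFrame, genes: pd.DataFrame,
                   snvs: pd.DataFrame | None = None,
                   config: FilterConfig | None = None) -> pd.DataFrame:
    sex = samples.set_index("sample_id")["sex"]
    labels = [classify(call, sex.get(call["sample_id"], "F"), genes, snvs, config)
              for _, call in calls.iterrows()]
    out = calls.copy()
    out["cnv_class"] = labels
    return out[out["cnv_class"].notna()].reset_index(drop=True)


# ----------------------------------------------------------------- double hit

def _double_hit_partner(call, snvs: pd.DataFrame, genes: pd.DataFrame) -> bool:
    return len(_double_hits_for_call(call, snvs, genes)) > 0


def _double_hits_for_call(call, snvs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    ar = genes[genes["inheritance"] == "AR"]
    over = _overlapping_genes(call, ar)
    if over.empty:
        return snvs.iloc[:0]
    m = (snvs["sample_id"].eq(call["sample_id"])
         & snvs["gene"].isin(over["symbol"])
         & snvs["pathogenic"].astype(bool)
         & snvs["zygosity"].str.lower().str.startswith("het"))
    return snvs[m]


def double_hit_match(calls: pd.DataFrame, snvs: pd.DataFrame,
                     genes: pd.DataFrame) -> pd.DataFrame:
    """Compound-heterozygote pairs: a heterozygous CNV deletion and a
    heterozygous pathogenic/high-impact SNV in the same biallelic (AR) gene
    of the same individual. Homozygous deletions are excluded (already
    explanatory alone)."""
    pairs = []
    for ci, call in calls.iterrows():
        if call["type"] != "DEL" or effective_copy_number(call) != 1:
            continue
        for _, snv in _double_hits_for_call(call, snvs, genes).iterrows():
            pairs.append(dict(sample_id=call["sample_id"], gene=snv["gene"],
                              cnv_index=ci, cnv_chrom=call["chrom"],
                              cnv_start=call["start"], cnv_end=call["end"],
                              snv_pos=snv.get("pos"), caller=call.get("caller")))
    return pd.DataFrame(pairs, columns=["sample_id", "gene", "cnv_index", "cnv_chrom",
                                        "cnv_start", "cnv_end", "snv_pos", "caller"])


# -------------------------------------------------------------- ERN strategies

def _multi_tool_flags(calls: pd.DataFrame, min_ro: float) -> np.ndarray:
    """True where another caller has a same-type call with >= min_ro
    reciprocal overlap in the same sample."""
    flags = np.zeros(len(calls), bool)
    arr = calls.reset_index(drop=True)
    for (_, _, _), grp in arr.groupby(["sample_id", "chrom", "type"], sort=False):
        s = grp["start"].to_numpy(float)
        e = grp["end"].to_numpy(float)
        caller = grp["caller"].to_numpy()
        pos = grp.index.to_numpy()
        for i in range(len(pos)):
            ro = reciprocal_overlap(s[i], e[i], s, e)
            if ((ro >= min_ro) & (caller != caller[i])).any():
                flags[pos[i]] = True
    return flags


def apply_ern_strategy(calls: pd.DataFrame, ern: str, genes: pd.DataFrame,
                       config: FilterConfig | None = None) -> pd.DataFrame:
    """Apply one ERN's prioritisation rules to classified calls.

    Adds columns: decision ('priority' | 'keep' | 'discard'), reason.
    Expects columns cnv_class, caller, quality, n_targets and the optional
    boolean annotation columns blacklist, benign, low_qc, plus de_novo.
    """
    config = config or FilterConfig()
    if ern not in ("EURO-NMD", "GENTURIS", "ITHACA", "RND"):
        raise ValueError(f"unknown ERN: {ern}")
    df = calls.reset_index(drop=True).copy()
    for col, default in (("blacklist", False), ("benign", False), ("low_qc", False),
                         ("de_novo", "unknown")):
        if col not in df:
            df[col] = default
        else:
            df[col] = df[col].fillna(default)
    multi = _multi_tool_flags(df, config.reciprocal_overlap)
    decision = np.array(["keep"] * len(df), dtype=object)
    reason = np.array([""] * len(df), dtype=object)
    length = (df["end"] - df["start"]).to_numpy()
    cn = df.apply(effective_copy_number, axis=1)
    is_long = df["cnv_class"].eq("LONG").to_numpy()

    def discard(mask, why):
        mask = np.asarray(mask, bool) & (decision != "discard")
        decision[mask] = "discard"
        reason[mask] = why

    def priority(mask, why):
        mask = np.asarray(mask, bool) & (decision == "keep")
        decision[mask] = "priority"
        reason[mask] = why

    if ern == "EURO-NMD":
        cfg = config.euro_nmd
        panel = _ern_genes(genes, ern)
        tolerant = np.zeros(len(df), bool)
        ar_only = np.zeros(len(df), bool)
        for i, call in df.iterrows():
            over = _overlapping_genes(call, panel)
            if over.empty:
                continue
            tolerant[i] = bool(((over["ddd_hi_score"] > cfg.hi_discard_above)
                                | (over["pli"] < cfg.pli_discard_below)).all())
            ar_only[i] = bool(over["inheritance"].eq("AR").all())
        discard((cn == 1).to_numpy() & tolerant & ~is_long,
                "HI>90 or pLI<0.1 (deletion-tolerant gene)")
        discard(df["caller"].eq("clincnv").to_numpy()
                & (df["quality"] < cfg.min_loglik).to_numpy()
                & cn.isin([1, 3]).to_numpy(), "clincnv loglik<30")
        discard(ar_only & ~is_long, "gene only recessive")
        discard(is_long & df["blacklist"].to_numpy(bool), "ENCODE blacklist")
    elif ern == "GENTURIS":
        cfg = config.genturis
        discard(is_long & df["blacklist"].to_numpy(bool), "ENCODE blacklist")
        priority(multi, "called by >1 tool")
        only_clin = ~multi & df["caller"].eq("clincnv").to_numpy()
        only_ed = ~multi & df["caller"].eq("exomedepth").to_numpy()
        discard(only_clin & (df["quality"] < cfg.min_loglik).to_numpy(),
                "clincnv-only loglik<20")
        discard(only_ed & (df["quality"] < cfg.min_bf).to_numpy(),
                "exomedepth-only BF<15")
    elif ern == "ITHACA":
        cfg = config.ithaca
        discard(df["low_qc"].to_numpy(bool), "low QC")
        discard(df["benign"].to_numpy(bool), "previously annotated benign")
        discard(df["blacklist"].to_numpy(bool), "ENCODE blacklist")
        exempt = (df["cnv_class"].eq("HOM_DEL").to_numpy()
                  | df["de_novo"].eq("de_novo").to_numpy())
        short_del = df["type"].eq("DEL").to_numpy() & (length < cfg.min_del_bp)
        short_dup = df["type"].eq("DUP").to_numpy() & (length < cfg.min_dup_bp)
        discard((short_del | short_dup) & ~exempt, "below minimum length")
        panel = _ern_genes(genes, ern)
        valid_gene = np.zeros(len(df), bool)
        for i, call in df.iterrows():
            over = _overlapping_genes(call, panel)
            valid_gene[i] = bool((over["validity_score"] >= cfg.min_validity).any())
        priority(valid_gene, "gene validity>=3")
        priority(length >= cfg.keep_regardless_bp, ">=200kb regardless of gene list")
    else:  # RND
        cfg = config.rnd
        clin = df["caller"].eq("clincnv").to_numpy()
        ed = df["caller"].eq("exomedepth").to_numpy()
        discard(clin & (df["quality"] < cfg.loglik_discard_below).to_numpy(),
                "clincnv loglik<30")
        priority(clin & (df["quality"] > cfg.loglik_priority_above).to_numpy(),
                 "clincnv loglik>200")
        discard(ed & ~multi
                & ((df["n_targets"] < cfg.min_targets).to_numpy()
                   | (df["quality"] < cfg.bf_discard_below).to_numpy()),
                "exomedepth <3 targets or BF<30 without support")
    df["decision"] = decision
    df["reason"] = reason
    df["multi_tool"] = multi
    return df
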