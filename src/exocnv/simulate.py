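"""Synthetic exome coverage cohorts with known copy-number ground truth.

The generator emulates the features of real multi-centre exome compendia that
drive CNV-calling behaviour: multiple enrichment kits with their own target
sets and depth distributions, GC-dependent capture bias, library-size
variation, batch structure within kits, negative-binomial count noise,
spiked CNVs of copy number 0–6 ranging from a single target to a whole
gonosome, parent–offspring trios with de novo events, and heterozygous SNVs
paired with heterozygous deletions on the other allele of recessive-disease
genes. Every downstream stage of the package is testable against the truth
tables it returns, without any sequence-level data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._genome import AUTOSOMES, CHROM_LENGTHS, PAR1_END, ploidy

#: Default mix of spiked-event footprints, from single-target events that only
#: a sensitive caller finds, up to whole-gonosome aneuploidies.
DEFAULT_LENGTH_DIST: Mapping[str, float] = {
    "1_target": 0.20,
    "2-3_targets": 0.30,
    "multi_target": 0.40,
    ">500kb": 0.08,
    "whole_chromosome": 0.02,
}

# Copy-number states for rare spiked events and their sampling weights.
_SPIKE_CN = np.array([0, 1, 3, 4, 5, 6])
_SPIKE_CN_W = np.array([0.10, 0.45, 0.30, 0.08, 0.05, 0.02])

_ANCESTRIES = ["EUR", "AFR", "EAS", "SAS", "AMR"]


@dataclass
class SimConfig:
    """Conditions for one simulated cohort.

    mean_depth_range is the range of per-sample library-size factors, i.e.
    the expected read count on a typical (weight-1) target. nb_dispersion is
    the negative-binomial overdispersion alpha in Var = mu + alpha*mu^2.
    fraction_common_cnv_loci is the carrier frequency planted at each common
    CNV locus, chosen so the cohort frequency filter has true positives to
    remove (>1% of samples).
    """

    n_kits: int = 1
    targets_per_kit: int = 2000
    samples_per_kit: int = 100
    target_length_range: tuple[int, int] = (120, 120)
    mean_depth_range: tuple[float, float] = (100.0, 200.0)
    gc_bias_strength: float = 0.3
    nb_dispersion: float = 0.01
    cnv_rate_per_sample: float = 1.5
    cnv_length_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    fraction_trios: float = 0.2
    fraction_common_cnv_loci: float = 0.05
    n_common_loci: int = 3
    batches_per_kit: int = 4
    batch_effect_sd: float = 0.40
    snv_partner_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_kits, self.targets_per_kit, self.samples_per_kit) < 1:
            raise ValueError("counts must be >= 1")
        for name in ("fraction_trios", "fraction_common_cnv_loci", "snv_partner_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.gc_bias_strength < 0:
            raise ValueError("gc_bias_strength must be >= 0")
        total = sum(self.cnv_length_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError("cnv_length_distribution must sum to 1")


@dataclass
class KitData:
    """Targets and raw counts for one enrichment kit."""

    kit_id: str
    targets: pd.DataFrame  # chrom, start, end, gc, kit_id; index = "chrom:start-end"
    counts: pd.DataFrame  # targets x samples, raw integer read counts


@dataclass
class SimulatedCohort:
    config: SimConfig
    kits: dict[str, KitData]
    samples: pd.DataFrame  # sample_id, family_id, affected, sex, kit_id, relationship, ...
    truth: pd.DataFrame  # sample_id, chrom, start, end, copy_number, de_novo, common_locus
    genes: pd.DataFrame  # gene panel with inheritance / pLI / HI / ERN annotations
    snvs: pd.DataFrame  # candidate SNVs for double-hit matching
    pairs: pd.DataFrame  # constructed (sample, gene) CNV+SNV double-hit ground truth


def target_index(targets: pd.DataFrame) -> pd.Index:
    return pd.Index(
        targets["chrom"].astype(str)
        + ":"
        + targets["start"].astype(str)
        + "-"
        + targets["end"].astype(str),
        name="target_id",
    )


def generate_targets(config: SimConfig, kit_id: str, rng: np.random.Generator) -> pd.DataFrame:
    """Sorted, non-overlapping capture targets for one kit across 1..22, X, Y.

    GC fractions are drawn from a capture-like Beta bulk plus a small
    (~0.3%) high-GC tail above 0.8 so the GC-extreme target filter has work
    to do on default settings.
    """
    config.validate()
    n = config.targets_per_kit
    chroms = AUTOSOMES + ["X", "Y"]
    lengths = np.array([CHROM_LENGTHS[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    # Exomes have proportionally few Y targets; damp Y, keep >= 5.
    weights[-1] *= 0.2
    weights /= weights.sum()
    n_per = rng.multinomial(n - 5, weights)
    n_per[-1] += 5

    rows = []
    for chrom, k in zip(chroms, n_per):
        if k == 0:
            continue
        span = CHROM_LENGTHS[chrom]
        lo, hi = config.target_length_range
        tlens = rng.integers(lo, hi + 1, size=k)
        # exonic clustering: mostly sub-kilobase gaps between probes of a
        # gene, occasionally large intergenic jumps
        intergenic = rng.random(k) < 0.2
        gaps = np.where(intergenic,
                        rng.lognormal(np.log(100_000), 1.0, size=k),
                        rng.lognormal(np.log(800), 0.8, size=k)).astype(np.int64) + 1
        total = gaps.sum() + tlens.sum()
        if total >= span:
            gaps = (gaps * (0.9 * (span - tlens.sum()) / gaps.sum())).astype(np.int64) + 1
        offset = int(rng.integers(0, max(span - gaps.sum() - tlens.sum(), 1)))
        starts = (offset + np.cumsum(gaps) + np.cumsum(tlens) - tlens).astype(np.int64)
        ends = starts + tlens
        gc = np.clip(rng.beta(20, 24, size=k), 0.05, 0.78)
        tail = rng.random(k) < 0.003
        gc[tail] = rng.uniform(0.82, 0.92, size=tail.sum())
        for s, e, g in zip(starts, ends, gc):
            rows.append((chrom, int(s), int(e), float(g), kit_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "kit_id"])
    df = df.sort_values(["chrom", "start"], key=_chrom_sort_key).reset_index(drop=True)
    df.index = target_index(df)
    return df


def _chrom_sort_key(col: pd.Series) -> pd.Series:
    order = {c: i for i, c in enumerate(AUTOSOMES + ["X", "Y"])}
    if col.name == "chrom":
        return col.map(order)
    return col


def _gc_factor(gc: np.ndarray, strength: float, optimum: float) -> np.ndarray:
    """Smooth unimodal multiplicative capture-efficiency curve in GC."""
    f = np.exp(-strength * ((gc - optimum) / 0.25) ** 2)
    return f / f.mean()


def generate_metadata(config: SimConfig, kit_id: str, start_index: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Families (trios and singletons) for one kit; each family has one
    affected proband, trio parents are unaffected relatives."""
    rows = []
    i = start_index
    kit_depth_lo, kit_depth_hi = config.mean_depth_range
    n_batches = max(1, config.batches_per_kit)
    while len(rows) < config.samples_per_kit:
        fam = f"FAM{i:05d}"
        is_trio = rng.random() < config.fraction_trios
        # batches are processing plates: contiguous blocks of samples, so
        # every batch has ~samples_per_kit / n_batches members
        batch = min(len(rows) * n_batches // config.samples_per_kit, n_batches - 1)
        ancestry = _ANCESTRIES[int(rng.integers(len(_ANCESTRIES)))]
        consang = bool(rng.random() < 0.05)
        sex = "M" if rng.random() < 0.5 else "F"
        depth = rng.uniform(kit_depth_lo, kit_depth_hi)
        rows.append((f"S{i:05d}", fam, True, sex, kit_id, "proband",
                     ancestry, batch, consang, depth))
        if is_trio and len(rows) + 2 <= config.samples_per_kit + 2:
            for rel, psex in (("mother", "F"), ("father", "M")):
                i += 1
                rows.append((f"S{i:05d}", fam, False, psex, kit_id, rel,
                             ancestry, batch, consang,
                             rng.uniform(kit_depth_lo, kit_depth_hi)))
        i += 1
    cols = ["sample_id", "family_id", "affected", "sex", "kit_id", "relationship",
            "ancestry_label", "batch", "consanguineous", "library_size"]
    df = pd.DataFrame(rows[: config.samples_per_kit], columns=cols)
    # a trio truncated by the cohort-size cap degrades to a duo/singleton;
    # keep relationship labels as-is (annotate_de_novo treats them as duos)
    return df


def _draw_event_span(category: str, chrom_targets: pd.DataFrame,
                     rng: np.random.Generator) -> tuple[int, int] | None:
    """Pick a contiguous run of target indices for a spiked event."""
    nt = len(chrom_targets)
    if nt == 0:
        return None
    if category == "1_target":
        k = 1
    elif category == "2-3_targets":
        k = int(rng.integers(2, 4))
    elif category == "multi_target":
        k = int(rng.integers(4, 11))
    elif category == ">500kb":
        # extend until genomic span exceeds 500 kb
        i0 = int(rng.integers(nt))
        starts = chrom_targets["start"].to_numpy()
        ends = chrom_targets["end"].to_numpy()
        j = i0
        while j < nt - 1 and ends[j] - starts[i0] <= 500_000:
            j += 1
        if ends[j] - starts[i0] <= 500_000:
            return None
        return i0, j + 1
    else:  # whole_chromosome
        return 0, nt
    if k > nt:
        return None
    i0 = int(rng.integers(nt - k + 1))
    return i0, i0 + k


def generate_truth(config: SimConfig, targets: pd.DataFrame, samples: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Spiked CNV events: rare per-sample events, inherited/de novo structure
    in trios, and designated common loci carried by a fixed fraction of
    samples (for the frequency filter to remove)."""
    cats = list(config.cnv_length_distribution)
    cat_p = np.array([config.cnv_length_distribution[c] for c in cats], float)
    cat_p = cat_p / cat_p.sum()
    by_chrom = {c: g.reset_index(drop=True) for c, g in targets.groupby("chrom", sort=False)}
    chrom_list = [c for c in AUTOSOMES + ["X", "Y"] if c in by_chrom]
    chrom_w = np.array([len(by_chrom[c]) for c in chrom_list], float)
    chrom_w /= chrom_w.sum()

    sample_sex = dict(zip(samples["sample_id"], samples["sex"]))
    fam_members: dict[str, list[str]] = {}
    for _, r in samples.iterrows():
        fam_members.setdefault(r["family_id"], []).append(r["sample_id"])
    parents_of = {}
    for _, r in samples.iterrows():
        if r["relationship"] == "proband":
            sibs = samples[(samples["family_id"] == r["family_id"])
                           & (samples["relationship"].isin(["mother", "father"]))]
            parents_of[r["sample_id"]] = list(sibs["sample_id"])

    records = []

    def place(sample_id: str, category: str, cn: int, de_novo: bool,
              common: bool, chrom: str | None = None) -> dict | None:
        if chrom is None:
            if category == "whole_chromosome":
                sex = sample_sex[sample_id]
                chrom = "X" if (sex == "F" or rng.random() < 0.7) else "Y"
            else:
                chrom = chrom_list[int(rng.choice(len(chrom_list), p=chrom_w))]
        ct = by_chrom[chrom]
        span = _draw_event_span(category, ct, rng)
        if span is None:
            return None
        i0, i1 = span
        return dict(sample_id=sample_id, chrom=chrom,
                    start=int(ct["start"].iloc[i0]), end=int(ct["end"].iloc[i1 - 1]),
                    copy_number=int(cn), de_novo=de_novo, common_locus=common,
                    n_targets=i1 - i0)

    # rare spikes
    for _, samp in samples.iterrows():
        sid = samp["sample_id"]
        if samp["relationship"] != "proband":
            continue  # parents only carry inherited copies + common loci
        n_events = rng.poisson(config.cnv_rate_per_sample)
        for _ in range(n_events):
            category = cats[int(rng.choice(len(cats), p=cat_p))]
            cn = int(rng.choice(_SPIKE_CN, p=_SPIKE_CN_W))
            if category == "whole_chromosome":
                # gonosomal aneuploidy: one extra or one missing copy
                rec = place(sid, category, 0, False, False)
                if rec is None:
                    continue
                base = ploidy(rec["chrom"], rec["start"], sample_sex[sid])
                if base == 0:
                    continue
                rec["copy_number"] = base + 1 if rng.random() < 0.8 else max(0, base - 1)
                if rec["copy_number"] == base:
                    continue
            else:
                rec = place(sid, category, cn, False, False)
                if rec is None:
                    continue
                base = ploidy(rec["chrom"], rec["start"], sample_sex[sid])
                if base == 0 or cn == base:
                    continue
                if rec["chrom"] in ("X", "Y") and cn > 1 and base == 1:
                    rec["copy_number"] = cn  # gains on hemizygous chromosomes
            par = parents_of.get(sid, [])
            if len(par) == 2:
                if rng.random() < 0.5:
                    rec["de_novo"] = True
                else:
                    carrier = par[int(rng.integers(2))]
                    base_p = ploidy(rec["chrom"], rec["start"], sample_sex[carrier])
                    if base_p > 0 and rec["copy_number"] != base_p:
                        inh = dict(rec, sample_id=carrier, de_novo=False)
                        records.append(inh)
            records.append(rec)

    # common loci: same-type event planted in a fixed fraction of samples
    autos = [c for c in chrom_list if c in AUTOSOMES]
    for li in range(config.n_common_loci):
        chrom = autos[int(rng.integers(len(autos)))]
        ct = by_chrom[chrom]
        span = _draw_event_span("multi_target", ct, rng)
        if span is None:
            continue
        i0, i1 = span
        cn = 1 if rng.random() < 0.5 else 3
        carriers = samples["sample_id"][
            rng.random(len(samples)) < config.fraction_common_cnv_loci
        ]
        for sid in carriers:
            if ploidy(chrom, int(ct["start"].iloc[i0]), sample_sex[sid]) != 2:
                continue
            records.append(dict(sample_id=sid, chrom=chrom,
                                start=int(ct["start"].iloc[i0]),
                                end=int(ct["end"].iloc[i1 - 1]),
                                copy_number=cn, de_novo=False, common_locus=True,
                                n_targets=i1 - i0))

    cols = ["sample_id", "chrom", "start", "end", "copy_number",
            "de_novo", "common_locus", "n_targets"]
    truth = pd.DataFrame(records, columns=cols)
    # drop overlapping events within a sample (keep first)
    keep = []
    seen: dict[str, list[tuple[str, int, int]]] = {}
    for idx, r in truth.iterrows():
        ivs = seen.setdefault(r["sample_id"], [])
        if any(c == r["chrom"] and r["start"] < e and s < r["end"] for c, s, e in ivs):
            keep.append(False)
        else:
            ivs.append((r["chrom"], r["start"], r["end"]))
            keep.append(True)
    return truth[np.array(keep, bool)].reset_index(drop=True)


def simulate_counts(targets: pd.DataFrame, samples: pd.DataFrame, truth: pd.DataFrame,
                    config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Raw read counts per target x sample.

    count ~ NegBin(mean = library_size * target_weight * gc_factor * CN/2,
    alpha = nb_dispersion); CN defaults to the sex-adjusted ploidy and is
    overridden on spiked intervals. De novo events live in the child only
    (generate_truth emits parental rows only for inherited events).
    """
    unknown = set(truth["chrom"]) - set(targets["chrom"])
    if unknown:
        raise ValueError(f"truth records on unknown chromosomes: {sorted(unknown)}")
    nt, ns = len(targets), len(samples)
    # probe capture efficiencies span an order of magnitude (lognormal),
    # shared by all samples of the kit
    weights = rng.lognormal(0.0, 0.7, size=nt)
    weights /= weights.mean()
    gc = targets["gc"].to_numpy()
    # every library has its own GC-bias curve (amplification chemistry and
    # fragment-size effects); batches shift the curve centre collectively
    n_batches = max(1, config.batches_per_kit)
    batch_opt = 0.45 + (0.05 * rng.standard_normal(n_batches) if n_batches > 1
                        else np.zeros(1))
    batch_strength = config.gc_bias_strength * (1.0 + 0.5 * rng.random(n_batches))

    chrom = targets["chrom"].to_numpy()
    start = targets["start"].to_numpy()

    cn = np.full((nt, ns), 2.0)
    from ._genome import PAR1_END
    x_hemi = (chrom == "X") & (start >= PAR1_END)
    y = chrom == "Y"
    male = (samples["sex"] == "M").to_numpy()
    cn[np.ix_(x_hemi, male)] = 1.0
    cn[np.ix_(y, male)] = 1.0
    cn[np.ix_(y, ~male)] = 0.0
    sample_pos = {sid: j for j, sid in enumerate(samples["sample_id"])}
    for _, ev in truth.iterrows():
        j = sample_pos.get(ev["sample_id"])
        if j is None:
            continue
        m = (chrom == ev["chrom"]) & (start >= ev["start"]) & (start < ev["end"])
        cn[m, j] = ev["copy_number"]

    lib = samples["library_size"].to_numpy()
    batch = samples["batch"].to_numpy() if "batch" in samples else np.zeros(ns, int)
    sample_opt = batch_opt[batch] + 0.05 * rng.standard_normal(ns)
    sample_strength = batch_strength[batch] * rng.lognormal(0.0, 0.5, size=ns)
    # each processing batch imprints its own multiplicative per-probe
    # efficiency profile (wet-lab batch effects); shared within the batch,
    # hence removable by batch-aware normalisation but inflating the pooled
    # per-target variance of the whole kit
    batch_profile = np.exp(config.batch_effect_sd * rng.standard_normal((n_batches, nt)))
    mu = np.empty((nt, ns))
    for j in range(ns):
        gf = _gc_factor(gc, sample_strength[j], sample_opt[j])
        mu[:, j] = lib[j] * weights * gf * batch_profile[batch[j]] * (cn[:, j] / 2.0)
    alpha = config.nb_dispersion
    nparam = 1.0 / alpha
    counts = np.zeros((nt, ns), dtype=np.int64)
    pos = mu > 0
    p = nparam / (nparam + mu[pos])
    counts[pos] = rng.negative_binomial(nparam, p)
    return pd.DataFrame(counts, index=targets.index, columns=list(samples["sample_id"]))


def generate_genes(targets: pd.DataFrame, rng: np.random.Generator,
                   coverage: float = 0.85) -> pd.DataFrame:
    """Gene panel laid over the target set: genes group 1-5 consecutive
    targets; annotations (inheritance mode, pLI, DDD HI score, ERN lists,
    validity score) drive the downstream prioritisation rules."""
    rows = []
    gi = 0
    erns = ["EURO-NMD", "GENTURIS", "ITHACA", "RND"]
    for chrom_name, ct in targets.groupby("chrom", sort=False):
        ct = ct.sort_values("start")
        i = 0
        nt = len(ct)
        while i < nt:
            if rng.random() > coverage:
                i += 1
                continue
            k = int(rng.integers(1, 6))
            j = min(i + k, nt)
            start = int(ct["start"].iloc[i]) - int(rng.integers(10, 200))
            end = int(ct["end"].iloc[j - 1]) + int(rng.integers(10, 200))
            if chrom_name == "X":
                inheritance = "XL"
            elif chrom_name == "Y":
                inheritance = "other"
            else:
                inheritance = ["AD", "AR", "other"][int(rng.choice(3, p=[0.4, 0.4, 0.2]))]
            membership = [e for e in erns if rng.random() < 0.5]
            if not membership and chrom_name != "Y":
                membership = [erns[int(rng.integers(4))]]
            if chrom_name == "Y":
                membership = []  # no genes of interest on Y in any ERN list
            rows.append((f"G{gi:05d}", f"GENE{gi:05d}", chrom_name, max(0, start), end,
                         ";".join(membership), inheritance,
                         float(rng.random()), float(rng.uniform(0, 100)),
                         int(rng.integers(1, 6))))
            gi += 1
            i = j
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end",
                                       "ern_lists", "inheritance", "pli",
                                       "ddd_hi_score", "validity_score"])


def generate_snv_partners(truth: pd.DataFrame, genes: pd.DataFrame, fraction: float,
                          rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heterozygous pathogenic SNV partners for a subset of heterozygous
    truth deletions in biallelic (AR) genes, plus decoy SNVs that must not
    be matched. Returns (snv table, constructed pairing ground truth)."""
    ar = genes[genes["inheritance"] == "AR"]
    snv_rows, pair_rows = [], []
    for _, ev in truth.iterrows():
        if ev["copy_number"] != 1 or ev["common_locus"] or ev["chrom"] in ("X", "Y"):
            continue
        hits = ar[(ar["chrom"] == ev["chrom"]) & (ar["start"] < ev["end"])
                  & (ev["start"] < ar["end"])]
        if hits.empty or rng.random() >= fraction:
            continue
        g = hits.iloc[0]
        pos = int(g["end"]) - 1
        snv_rows.append((ev["sample_id"], g["symbol"], ev["chrom"], pos,
                         "het", True, "pathogenic_partner"))
        pair_rows.append((ev["sample_id"], g["symbol"], ev["chrom"],
                          int(ev["start"]), int(ev["end"])))
    # decoys: pathogenic SNV in an AD gene, benign SNV in an AR gene
    ad = genes[genes["inheritance"] == "AD"]
    samples_seen = truth["sample_id"].unique()
    for kind, pool, flag in (("decoy_ad", ad, True), ("decoy_benign", ar, False)):
        if len(pool) and len(samples_seen):
            g = pool.iloc[int(rng.integers(len(pool)))]
            sid = samples_seen[int(rng.integers(len(samples_seen)))]
            snv_rows.append((sid, g["symbol"], g["chrom"], int(g["start"]) + 5,
                             "het", flag, kind))
    snvs = pd.DataFrame(snv_rows, columns=["sample_id", "gene", "chrom", "pos",
                                           "zygosity", "pathogenic", "note"])
    pairs = pd.DataFrame(pair_rows, columns=["sample_id", "gene", "chrom",
                                             "cnv_start", "cnv_end"])
    return snvs, pairs


class CohortSimulator:
    """End-to-end generator. A fixed seed fully determines every output."""

    def __init__(self, config: SimConfig | None = None, **overrides):
        if config is None:
            config = SimConfig(**overrides)
        elif overrides:
            config = dataclasses.replace(config, **overrides)
        config.validate()
        self.config = config

    def run(self) -> SimulatedCohort:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        kits: dict[str, KitData] = {}
        all_samples, all_truth = [], []
        genes = None
        idx0 = 0
        for ki in range(cfg.n_kits):
            kit_id = f"KIT{ki + 1}"
            targets = generate_targets(cfg, kit_id, rng)
            samples = generate_metadata(cfg, kit_id, idx0, rng)
            idx0 += len(samples) + 10
            truth = generate_truth(cfg, targets, samples, rng)
            counts = simulate_counts(targets, samples, truth, cfg, rng)
            kits[kit_id] = KitData(kit_id, targets, counts)
            all_samples.append(samples)
            all_truth.append(truth)
            if genes is None:
                genes = generate_genes(targets, rng)
        samples = pd.concat(all_samples, ignore_index=True)
        truth = pd.concat(all_truth, ignore_index=True)
        snvs, pairs = generate_snv_partners(truth, genes, cfg.snv_partner_fraction, rng)
        return SimulatedCohort(cfg, kits, samples, truth, genes, snvs, pairs)


def naive_copy_number_oracle(counts: pd.DataFrame) -> pd.DataFrame:
    """Independent copy-number check used to validate the callers:
    library-normalise each sample by its median ratio to the cohort median
    profile, then round 2x the per-target ratio to the cohort median.
    Reliable for events spanning >=3 targets at low dispersion."""
    ref = counts.median(axis=1)
    ok = ref > 0
    ratios = counts[ok].div(ref[ok], axis=0)
    lib = ratios.median(axis=0)
    norm = ratios.div(lib, axis=1)
    cn = (2.0 * norm).round().astype(int)
    return cn.reindex(counts.index)
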