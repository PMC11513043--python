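"""Nomenclature, summary tables and the packaged expert-curated CNV catalog.

The catalog (``data/cnv_catalog.tsv``) is a transcription of the published
table of 111 expert-reviewed records from a large European multi-centre
rare-disease exome reanalysis: 103 potentially pathogenic CNVs (52 confirmed
disease-causing, 25 partially explanatory including 7 whole-gonosome
aneuploidies, 26 unvalidated candidates) plus the 8 SNVs forming
compound-heterozygous double-hits with catalogued CNVs.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ._genome import GRCH37_ACCESSIONS
from ._util import round_half_up

#: Copy-number categories of the cohort summary table.
SUMMARY_CATEGORIES = ["Long", "0", "1", "2", "3", "4", ">4"]


def cnv_length(start: int, end: int) -> int:
    """Length of a CNV in bp under 0-based half-open convention: end - start."""
    if end <= start:
        raise ValueError(f"end must exceed start, got {start}..{end}")
    return end - start


def hgvs_name(chrom: str, start: int, end: int, cnv_type: str, cn,
              zygosity: str = "Heterozygous") -> str:
    """Uncertain-breakpoint HGVS-style name for an exome CNV call.

    Heterozygous deletions -> ``ACC:g.(?_start)_(end_?)del``; duplications of
    copy number 3 (or hemizygous 2) -> ``...dup``; copy numbers 0, 4 and
    above carry an explicit bracketed copy number, e.g. ``...[0]``.
    """
    acc = GRCH37_ACCESSIONS.get(str(chrom))
    if acc is None:
        raise KeyError(f"no accession for chromosome {chrom!r}")
    cn_num = None if cn in (None, "NA") else int(cn)
    if cn_num is not None and (cn_num == 0 or cn_num >= 4):
        suffix = f"[{cn_num}]"
    elif cnv_type == "DEL":
        suffix = "del"
    else:
        suffix = "dup"
    return f"{acc}:g.(?_{start})_({end}_?){suffix}"


def aneuploidy_name(karyotype: str) -> str:
    """Whole-gonosome aneuploidy name, e.g. 47,XXY -> NC_000023.10:g.pter_qter[2]."""
    sexchrom = karyotype.split(",")[1]
    for gono in ("X", "Y"):
        n = sexchrom.count(gono)
        if n > 1:
            return f"{GRCH37_ACCESSIONS[gono]}:g.pter_qter[{n}]"
    raise ValueError(f"not an aneuploid gonosomal karyotype: {karyotype}")


def load_cnv_catalog() -> pd.DataFrame:
    """The packaged expert-curated CNV/SNV catalog as a DataFrame (all
    columns as strings; NA entries are the literal string 'NA')."""
    with resources.files("exocnv.data").joinpath("cnv_catalog.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def catalog_cnvs(catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """CNV rows of the catalog (excludes SNV partners) with numeric coordinates."""
    cat = load_cnv_catalog() if catalog is None else catalog
    cnv = cat[cat["variant_kind"].isin(["CNV", "CNV-DNM", "CNV1of2", "Aneuploidy"])].copy()
    for col in ("start", "end", "length"):
        cnv[col] = pd.to_numeric(cnv[col], errors="coerce")
    return cnv


def summarize_calls(calls: pd.DataFrame, long_cnv_bp: int = 500_000) -> pd.DataFrame:
    """Cohort summary: rows = caller, columns = copy-number category
    (Long, 0..4, >4), cell = 'count (gonosomal subcount)' counts kept as a
    MultiIndex frame with 'total' and 'gonosomal' levels, plus Total and
    percentage-of-events rows."""
    df = calls.copy()
    length = df["end"] - df["start"]
    cn = df.apply(lambda c: _summary_category(c, c["end"] - c["start"], long_cnv_bp), axis=1) \
        if len(df) else pd.Series(dtype=object)
    df["category"] = cn
    df["gonosomal"] = df["chrom"].isin(["X", "Y"]) if len(df) else False
    callers = sorted(df["caller"].unique()) if len(df) else []
    total = pd.DataFrame(0, index=callers + ["Total"], columns=SUMMARY_CATEGORIES)
    gono = total.copy()
    for caller, grp in df.groupby("caller"):
        for cat, sub in grp.groupby("category"):
            total.loc[caller, cat] = len(sub)
            gono.loc[caller, cat] = int(sub["gonosomal"].sum())
    total.loc["Total"] = total.loc[callers].sum() if callers else 0
    gono.loc["Total"] = gono.loc[callers].sum() if callers else 0
    out = pd.concat({"total": total, "gonosomal": gono}, axis=1)
    grand = out[("total",)].loc["Total"].sum()
    pct = percent_of_events(out.loc["Total", "total"].to_numpy()) if grand else \
        [0.0] * len(SUMMARY_CATEGORIES)
    out.loc["% of Events"] = 0.0
    out.loc["% of Events", [("total", c) for c in SUMMARY_CATEGORIES]] = pct
    return out


def _summary_category(call, length: int, long_cnv_bp: int) -> str:
    if length > long_cnv_bp:
        return "Long"
    cn = call.get("copy_number")
    if cn is pd.NA or cn is None or (isinstance(cn, float) and np.isnan(cn)):
        cn = 1 if call["type"] == "DEL" else 3
    if cn == "OTHER" or (not isinstance(cn, str) and cn > 4):
        return ">4"
    return str(int(cn))


def percent_of_events(counts) -> list[float]:
    """Percentages of the grand total, half-up to 2 decimals (the printed
    convention of cohort summary tables)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty summary")
    return [round_half_up(100.0 * c / total, 2) for c in counts]


def diagnostic_yield(solved_families: int, total_families: int) -> float:
    """Percentage of families with a disease-causing variant, one decimal."""
    if total_families <= 0:
        raise ValueError("total_families must be > 0")
    if solved_families < 0:
        raise ValueError("solved_families must be >= 0")
    return round_half_up(100.0 * solved_families / total_families, 1)
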