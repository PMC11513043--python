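"""Readers and writers for the package's plain-text interchange formats.

Targets travel as BED (0-based half-open, with GC and kit columns), count
matrices and tables as TSV (gzip accepted via pandas/numpy inference), and
call tracks additionally as SEG for genome browsers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import target_index


def write_targets_bed(targets: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    extra = [c for c in ("gc", "kit_id", "target_id") if c in targets.columns]
    targets[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_targets_bed(path: str | Path, kit_id: str = "KIT1") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        df = df.rename(columns={3: "gc"})
    if df.shape[1] > 4:
        df = df.rename(columns={4: "kit_id"})
    else:
        df["kit_id"] = kit_id
    df.index = target_index(df)
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="target_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="target_id")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_seg(calls: pd.DataFrame, path: str | Path) -> None:
    """SEG track: sample, chrom, start, end, n_windows, seg value (the
    caller's quality metric, signed negative for deletions)."""
    seg = pd.DataFrame({
        "ID": calls["sample_id"],
        "chrom": calls["chrom"],
        "loc.start": calls["start"],
        "loc.end": calls["end"],
        "num.mark": calls["n_windows"],
        "seg.mean": [q if t == "DUP" else -q
                     for q, t in zip(calls["quality"], calls["type"])],
    })
    seg.to_csv(path, sep="\t", index=False)
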