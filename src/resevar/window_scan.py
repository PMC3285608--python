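"""Sliding-window variation-frequency profiles and high/low region calling.

Windows of 100 kb advance in 50 kb steps along each chromosome.  The
variation frequency of a window is the variant count divided by the number
of *covered* bases inside it (uncovered nucleotides are excluded from the
denominator).  The genome-wide average rate (ARG) is the arithmetic mean of
the frequencies over all unmasked windows of all chromosomes; a window is
called *high* when its rate exceeds four times the ARG and *low* when it
falls below one twentieth of the ARG, both strict inequalities.  The
deviation ratio (DR) of a window is the sum over samples of the ratio of
each sample's rate to the ARG; it is reported as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CoverageMask, GenomeSequence, ResevarError, VariantRecord
from .comparison import _category  # noqa: F401  (shared category labels)


@dataclass
class RegionCall:
    """A maximal run of same-label windows in one scope."""

    chrom: str
    start: int
    end: int
    label: str  # 'high' | 'low'
    category: str
    scope: str  # sample name, or '&'-joined sample names for intersections


def make_windows(length: int, window: int = 100_000, step: int = 50_000) -> list[tuple[int, int]]:
    """Window spans for one chromosome.

    Starts at 0, ``step``, 2*``step``, ...; the final partial window is
    emitted truncated when at least ``step`` bases remain, otherwise
    dropped.
    """
    if window % step != 0:
        raise ResevarError(f"window {window} is not a multiple of step {step}")
    out = []
    for s in range(0, length, step):
        remaining = length - s
        if remaining >= window:
            out.append((s, s + window))
        elif remaining >= step:
            out.append((s, length))
    if not out and length > 0:
        out.append((0, length))
    return out


def window_frequencies(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    masks: Mapping[str, CoverageMask],
    genome: GenomeSequence,
    window: int = 100_000,
    step: int = 50_000,
    min_covered_frac: float = 0.1,
) -> pd.DataFrame:
    """Windowed variant counts and frequencies per sample and category.

    A variant is counted in every window containing its position (at most
    two for a half-window step).  Windows whose covered-base count falls
    below ``min_covered_frac`` of the window length are masked: their
    frequency is NaN and they are excluded from the ARG and from region
    calling.
    """
    rows = []
    for sample, recs in variant_sets.items():
        mask = masks[sample]
        pos_by = {}
        for r in recs:
            pos_by.setdefault((r.chrom, _category(r.vtype)), []).append(r.pos)
        sorted_pos = {k: np.sort(np.asarray(v)) for k, v in pos_by.items()}
        for chrom, length in genome.lengths.items():
            for ws, we in make_windows(length, window, step):
                covered = mask.covered_in_window(chrom, ws, we)
                masked = covered < min_covered_frac * (we - ws)
                for cat in ("SNP", "InDel", "SV"):
                    pos = sorted_pos.get((chrom, cat))
                    if pos is None:
                        n = 0
                    else:
                        n = int(
                            np.searchsorted(pos, we, side="left")
                            - np.searchsorted(pos, ws, side="left")
                        )
                    freq = np.nan if masked else n / covered
                    rows.append(
                        {
                            "sample": sample,
                            "chrom": chrom,
                            "start": ws,
                            "end": we,
                            "category": cat,
                            "count": n,
                            "covered": covered,
                            "freq": freq,
                        }
                    )
    return pd.DataFrame(rows)


def compute_arg(wstats: pd.DataFrame) -> dict[str, float]:
    """Average variation rate over the whole genome, per variant category.

    Arithmetic mean of the unmasked window frequencies across chromosomes,
    pooled over samples.
    """
    out: dict[str, float] = {}
    for cat, sub in wstats.groupby("category"):
        vals = sub["freq"].dropna()
        if vals.empty:
            raise ResevarError(f"all windows masked for category {cat}")
        out[cat] = float(vals.mean())
    return out


def compute_dr(wstats: pd.DataFrame, arg: Mapping[str, float]) -> pd.DataFrame:
    """Deviation ratio per window: sum over samples of rate / ARG."""
    df = wstats.copy()
    df["ratio"] = df.apply(
        lambda r: r["freq"] / arg[r["category"]] if arg.get(r["category"]) else np.nan,
        axis=1,
    )
    out = (
        df.groupby(["chrom", "start", "end", "category"], as_index=False)["ratio"]
        .sum(min_count=1)
        .rename(columns={"ratio": "dr"})
    )
    return out


def _merge_windows(
    labelled: list[tuple[str, int, int, str]], category: str, scope: str
) -> list[RegionCall]:
    """Merge adjacent/overlapping same-label windows into regions."""
    labelled.sort()
    regions: list[RegionCall] = []
    for chrom, s, e, lab in labelled:
        last = regions[-1] if regions else None
        if (
            last is not None
            and last.chrom == chrom
            and last.label == lab
            and s <= last.end
        ):
            last.end = max(last.end, e)
        else:
            regions.append(RegionCall(chrom, s, e, lab, category, scope))
    return regions


def label_windows(
    wstats: pd.DataFrame,
    arg: Mapping[str, float],
    high_fold: float = 4.0,
    low_fold: float = 20.0,
) -> pd.DataFrame:
    """Per-window high/low labels per sample (strict inequalities);
    boundary-equal and masked windows stay unlabelled."""
    df = wstats.copy()

    def lab(row):
        f = row["freq"]
        if np.isnan(f):
            return None
        a = arg[row["category"]]
        if f > high_fold * a:
            return "high"
        if f < a / low_fold:
            return "low"
        return None

    df["label"] = df.apply(lab, axis=1)
    return df


def call_regions(
    wstats: pd.DataFrame,
    arg: Mapping[str, float],
    high_fold: float = 4.0,
    low_fold: float = 20.0,
) -> list[RegionCall]:
    """Per-sample high/low variation regions (adjacent windows merged)."""
    df = label_windows(wstats, arg, high_fold, low_fold)
    regions: list[RegionCall] = []
    for (sample, cat), sub in df.groupby(["sample", "category"]):
        lab = sub[sub["label"].notna()]
        windows = [
            (r["chrom"], int(r["start"]), int(r["end"]), r["label"])
            for _, r in lab.iterrows()
        ]
        for label in ("high", "low"):
            regions += _merge_windows(
                [w for w in windows if w[3] == label], cat, sample
            )
    return regions


def intersect_regions(
    wstats: pd.DataFrame,
    arg: Mapping[str, float],
    samples: Sequence[str],
    high_fold: float = 4.0,
    low_fold: float = 20.0,
) -> list[RegionCall]:
    """Windows where every in-scope sample carries the same label, merged
    into regions; this is the identical-region rule between samples."""
    df = label_windows(wstats, arg, high_fold, low_fold)
    df = df[df["sample"].isin(samples)]
    scope = "&".join(samples)
    regions: list[RegionCall] = []
    for cat, sub in df.groupby("category"):
        pivot = sub.pivot_table(
            index=["chrom", "start", "end"],
            columns="sample",
            values="label",
            aggfunc="first",
        )
        shared = []
        for (chrom, s, e), row in pivot.iterrows():
            labels = [row.get(smp) for smp in samples]
            if all(isinstance(l, str) for l in labels) and len(set(labels)) == 1:
                shared.append((chrom, int(s), int(e), labels[0]))
        for label in ("high", "low"):
            regions += _merge_windows(
                [w for w in shared if w[3] == label], cat, scope
            )
    return regions
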