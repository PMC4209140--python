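"""Joining per-site selection posteriors with disease-mutation counts and
summarizing protein-stability (ddG) tables by substitution class.

The mutation analysis asks how the per-residue posterior probability of
positive / neutral / negative selection relates to the number of reported
disease-causing missense mutations at that residue.  The default regression
mode bins residues by mutation count, averages each aggregate posterior
within bins, and correlates the bin means against the count (Pearson); a
per-site mode correlates across residues directly.

ddG is the change in folding free energy on substitution (kcal/mol,
positive = destabilizing); tables carry one of three substitution classes:
``all19`` (every possible replacement), ``evolutionary`` (replacements seen
across species) and ``disease`` (reported pathogenic mutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DDG_CLASSES = ("all19", "evolutionary", "disease")


def read_mutation_table(path) -> pd.DataFrame:
    """TSV with columns position (1-based residue) and count."""
    frame = pd.read_csv(path, sep="\t")
    return validate_mutation_table(frame)


def validate_mutation_table(frame: pd.DataFrame) -> pd.DataFrame:
    if not {"position", "count"} <= set(frame.columns):
        raise ValueError("mutation table needs 'position' and 'count' columns")
    if frame["position"].duplicated().any():
        raise ValueError("duplicate residue positions in mutation table")
    if (frame["count"] < 0).any():
        raise ValueError("mutation counts must be non-negative")
    return frame


def read_stability_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    return validate_stability_table(frame)


def validate_stability_table(frame: pd.DataFrame) -> pd.DataFrame:
    required = {"position", "from_aa", "to_aa", "class", "ddg"}
    if not required <= set(frame.columns):
        raise ValueError(f"stability table needs columns {sorted(required)}")
    unknown = set(frame["class"]) - set(DDG_CLASSES)
    if unknown:
        raise ValueError(f"unknown ddG classes: {sorted(unknown)}")
    if (frame["from_aa"] == frame["to_aa"]).any():
        raise ValueError("from_aa must differ from to_aa")
    return frame


def map_alignment_to_reference(aln, ref_taxon: str, *, numbering_offset: int = 0) -> dict[int, int]:
    """1-based alignment codon column -> 1-based ungapped residue index of
    the reference row; columns where the reference is gapped are absent.

    Numbering uses full-length coordinates (initiator Met = 1) by default.
    ``numbering_offset`` subtracts a fixed shift for legacy mature-protein
    numbering (common in hemophilia mutation databases, where numbering
    starts after the signal/propeptide); columns that would map to residue
    numbers < 1 are dropped.
    """
    if ref_taxon not in aln.taxa:
        raise KeyError(f"reference taxon {ref_taxon!r} not in alignment")
    seq = aln.sequences[aln.taxa.index(ref_taxon)]
    mapping: dict[int, int] = {}
    residue = 0
    for s in range(aln.n_sites):
        codon = seq[3 * s : 3 * s + 3]
        if "-" in codon:
            continue
        residue += 1
        if residue - numbering_offset >= 1:
            mapping[s + 1] = residue - numbering_offset
    return mapping


@dataclass
class CorrelationResult:
    """Pearson correlations of aggregate selection posteriors vs mutation
    counts, one per selection category."""

    mode: str
    n_points: int
    r_positive: float | None
    r_neutral: float | None
    r_negative: float | None
    slope_positive: float | None = None
    slope_neutral: float | None = None
    slope_negative: float | None = None
    intercept_positive: float | None = None
    intercept_neutral: float | None = None
    intercept_negative: float | None = None
    undefined: list[str] = None

    def __post_init__(self):
        if self.undefined is None:
            self.undefined = []

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in ("positive", "neutral", "negative"):
            rows.append(
                {
                    "category": cat,
                    "r": getattr(self, f"r_{cat}"),
                    "slope": getattr(self, f"slope_{cat}"),
                    "intercept": getattr(self, f"intercept_{cat}"),
                    "defined": cat not in self.undefined,
                }
            )
        return pd.DataFrame(rows)


def selection_mutation_regression(
    posteriors,
    mutations: pd.DataFrame,
    *,
    mode: str = "binned",
    missing_count: str = "zero",
) -> CorrelationResult:
    """Correlate selection posteriors with disease-mutation counts.

    ``posteriors`` is a SitePosterior (or its to_frame() output) whose site
    numbers share the coordinate system of ``mutations['position']`` (use
    ``map_alignment_to_reference`` to convert first if needed).  Sites
    absent from the mutation table get count 0 by default
    (``missing_count='zero'``) or are excluded (``'drop'``).
    """
    if mode not in ("binned", "per_site"):
        raise ValueError("mode must be 'binned' or 'per_site'")
    frame = posteriors.to_frame() if hasattr(posteriors, "to_frame") else posteriors.copy()
    mutations = validate_mutation_table(mutations)
    merged = frame.merge(
        mutations.rename(columns={"position": "site"}), on="site", how="left"
    )
    if missing_count == "zero":
        merged["count"] = merged["count"].fillna(0)
    elif missing_count == "drop":
        merged = merged.dropna(subset=["count"])
    else:
        raise ValueError("missing_count must be 'zero' or 'drop'")
    if len(merged) < 3:
        raise ValueError("need at least 3 joined sites")

    if mode == "binned":
        data = merged.groupby("count", as_index=False)[
            ["p_positive", "p_neutral", "p_negative"]
        ].mean()
        x = data["count"].to_numpy(float)
    else:
        data = merged
        x = merged["count"].to_numpy(float)

    out = {"mode": mode, "n_points": len(data), "undefined": []}
    for cat in ("positive", "neutral", "negative"):
        y = data[f"p_{cat}"].to_numpy(float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[f"r_{cat}"] = None
            out["undefined"].append(cat)
            continue
        r = float(stats.pearsonr(x, y).statistic)
        slope, intercept = np.polyfit(x, y, 1)
        out[f"r_{cat}"] = r
        out[f"slope_{cat}"] = float(slope)
        out[f"intercept_{cat}"] = float(intercept)
    return CorrelationResult(**out)


def clip_for_display(table: pd.DataFrame, cap: float = 10.0) -> pd.DataFrame:
    """Copy of a ddG table with values capped at ``cap`` kcal/mol for
    plotting; never feed the result to ``stability_class_summary``."""
    out = table.copy()
    out["ddg"] = out["ddg"].clip(upper=cap)
    return out


def stability_class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median, quartiles and n of ddG per substitution class.

    Statistics are computed on unclipped values (use ``clip_for_display``
    only for visualization).  Classes with no rows are simply absent from
    the output.
    """
    table = validate_stability_table(table)
    rows = []
    for cls in DDG_CLASSES:
        vals = table.loc[table["class"] == cls, "ddg"].to_numpy(float)
        if len(vals) == 0:
            continue
        rows.append(
            {
                "class": cls,
                "n": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(rows)
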