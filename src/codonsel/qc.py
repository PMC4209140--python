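"""Pre-analysis quality control: sequence filtering, tree pruning, and a
codon-aware conserved-block filter.

The block filter is a deliberately simplified stand-in for Gblocks-style
trimming: codon columns are classified by majority identity, gap-rich
columns (more than half the rows gapped) are dropped, and surviving
conserved columns are kept only in runs of a minimum block length.  It is
codon-granular (never splits codons) and reports a 1-based column map back
to the input alignment; bit-exact fidelity to Gblocks is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignment import CodonAlignment


@dataclass
class QCReport:
    kept_taxa: list[str] = field(default_factory=list)
    removed_taxa: dict[str, str] = field(default_factory=dict)  # taxon -> reason
    column_map: list[int] = field(default_factory=list)  # filtered col (1-based order) -> original col (1-based)
    parameters: dict = field(default_factory=dict)
    notes: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{"taxon": t, "kept": True, "reason": ""} for t in self.kept_taxa]
        rows += [
            {"taxon": t, "kept": False, "reason": r} for t, r in self.removed_taxa.items()
        ]
        return pd.DataFrame(rows)


def filter_sequences(
    aln: CodonAlignment, max_ambiguous_fraction: float = 0.01
) -> tuple[CodonAlignment, QCReport]:
    """Drop rows whose fraction of N over non-gap positions is strictly
    greater than the threshold (the '>1% unknown nucleotides' rule)."""
    report = QCReport(parameters={"max_ambiguous_fraction": max_ambiguous_fraction})
    keep = []
    for name, seq in zip(aln.taxa, aln.sequences):
        non_gap = sum(1 for c in seq if c != "-")
        n_count = seq.count("N")
        frac = n_count / non_gap if non_gap else 1.0
        if frac > max_ambiguous_fraction:
            report.removed_taxa[name] = f"ambiguous fraction {frac:.4f} > {max_ambiguous_fraction}"
        else:
            keep.append(name)
    if not keep:
        raise ValueError("all sequences removed by the ambiguity filter")
    report.kept_taxa = keep
    report.column_map = list(range(1, aln.n_sites + 1))
    return aln.subset_taxa(keep), report


def prune_tree(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Restrict a tree to ``keep`` taxa, collapsing the resulting degree-2
    nodes with their branch lengths summed."""
    keep = list(keep)
    if len(keep) < 2:
        raise ValueError("at least two taxa must be kept")
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = [t for t in keep if t not in labels]
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    return pruned


def conserved_block_filter(
    aln: CodonAlignment,
    *,
    min_identity: float = 0.5,
    max_gap_fraction: float = 0.5,
    min_block_length: int = 4,
) -> tuple[CodonAlignment, QCReport]:
    """Keep runs (>= ``min_block_length``) of conserved codon columns.

    A codon column is *conserved* when its most frequent fully resolved
    codon accounts for strictly more than ``min_identity`` of the rows, and
    its fraction of gapped rows does not exceed ``max_gap_fraction`` (the
    half-gap rule).
    """
    if aln.n_taxa < 4:
        raise ValueError("block filtering needs at least 4 sequences")
    n = aln.n_taxa
    good = np.zeros(aln.n_sites, dtype=bool)
    for s in range(aln.n_sites):
        codons = [seq[3 * s : 3 * s + 3] for seq in aln.sequences]
        gapped = sum(1 for c in codons if "-" in c)
        if gapped / n > max_gap_fraction:
            continue
        resolved = [c for c in codons if "-" not in c and "N" not in c]
        if not resolved:
            continue
        top = max(resolved.count(c) for c in set(resolved))
        if top / n > min_identity:
            good[s] = True

    kept: list[int] = []
    run: list[int] = []
    for s in range(aln.n_sites):
        if good[s]:
            run.append(s)
        else:
            if len(run) >= min_block_length:
                kept.extend(run)
            run = []
    if len(run) >= min_block_length:
        kept.extend(run)
    if not kept:
        raise ValueError("no codon columns survive the block filter")

    report = QCReport(
        kept_taxa=list(aln.taxa),
        column_map=[s + 1 for s in kept],
        parameters={
            "min_identity": min_identity,
            "max_gap_fraction": max_gap_fraction,
            "min_block_length": min_block_length,
        },
        notes=(
            "simplified conserved-block filter (majority-identity + half-gap "
            "rule); not a bit-exact Gblocks reimplementation"
        ),
    )
    return aln.subset_sites(kept), report
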