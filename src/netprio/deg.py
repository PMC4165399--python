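"""Fold-change screening of differentially expressed genes (DEGs).

Two normalized expression profiles (one per condition, linear intensity
scale) are compared gene by gene; a gene is called differentially expressed
when the case/control ratio reaches a symmetric fold-change threshold:
up if ratio >= t, down if ratio <= 1/t, with the boundary inclusive.  The
default threshold is 1.5.  No replicate statistics are involved — the screen
is a pure ratio filter, which is all the single-profile design supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

DEFAULT_THRESHOLD = 1.5


@dataclass(frozen=True)
class ExpressionPair:
    """Paired normalized intensities for one case/control contrast.

    Intensities are linear-scale (post-normalization) and strictly positive;
    ``genes`` are unique symbols aligned with both vectors.
    """

    genes: tuple[str, ...]
    control: np.ndarray
    case: np.ndarray
    labels: tuple[str, str] = ("control", "case")

    def __post_init__(self) -> None:
        control = np.asarray(self.control, dtype=float)
        case = np.asarray(self.case, dtype=float)
        object.__setattr__(self, "control", control)
        object.__setattr__(self, "case", case)
        if len(self.genes) != len(control) or len(self.genes) != len(case):
            raise InvalidInputError("genes, control and case must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidInputError("gene symbols must be unique")
        if not (np.all(control > 0) and np.all(case > 0)):
            raise InvalidInputError("all intensities must be strictly positive")

    def swapped(self) -> "ExpressionPair":
        """The same contrast with case and control exchanged."""
        return ExpressionPair(self.genes, self.case, self.control,
                              (self.labels[1], self.labels[0]))


@dataclass(frozen=True)
class DEGTable:
    """Called DEGs: a frame with columns gene, fold_change, log2_fc, direction.

    Sorted by \\|log2 fold change\\| descending, ties broken by symbol.
    """

    frame: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD
    labels: tuple[str, str] = field(default=("control", "case"))

    @property
    def genes(self) -> set[str]:
        return set(self.frame["gene"])

    @property
    def up_genes(self) -> set[str]:
        return set(self.frame.loc[self.frame["direction"] == "up", "gene"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.frame.loc[self.frame["direction"] == "down", "gene"])

    @property
    def directions(self) -> dict[str, str]:
        return dict(zip(self.frame["gene"], self.frame["direction"]))

    def __len__(self) -> int:
        return len(self.frame)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def compute_fold_changes(pair: ExpressionPair) -> dict[str, float]:
    """Per-gene case/control ratio on the linear scale (strictly positive)."""
    ratios = pair.case / pair.control
    return dict(zip(pair.genes, ratios.tolist()))


def call_degs(
    fold_changes: Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
    labels: tuple[str, str] = ("control", "case"),
) -> DEGTable:
    """Call up/down DEGs at a symmetric ratio threshold (boundary inclusive).

    up: ratio >= threshold; down: ratio <= 1/threshold; everything else is
    excluded from the table.
    """
    if not threshold > 1:
        raise InvalidParameterError(f"threshold must exceed 1, got {threshold}")
    rows = []
    for gene, fc in fold_changes.items():
        if fc <= 0:
            raise InvalidInputError(f"fold change for {gene} is not positive: {fc}")
        if fc >= threshold:
            rows.append((gene, fc, np.log2(fc), "up"))
        elif fc <= 1.0 / threshold:
            rows.append((gene, fc, np.log2(fc), "down"))
    frame = pd.DataFrame(rows, columns=["gene", "fold_change", "log2_fc", "direction"])
    if len(frame):
        frame = frame.sort_values(
            ["log2_fc", "gene"],
            key=lambda s: s.abs() if s.name == "log2_fc" else s,
            ascending=[False, True],
        ).reset_index(drop=True)
    return DEGTable(frame, threshold=threshold, labels=labels)


def degs_from_pair(pair: ExpressionPair, threshold: float = DEFAULT_THRESHOLD) -> DEGTable:
    """Convenience: fold changes + call in one step."""
    return call_degs(compute_fold_changes(pair), threshold, labels=pair.labels)


def contrast_profiles(
    pair_a: ExpressionPair,
    pair_b: ExpressionPair,
    threshold: float = DEFAULT_THRESHOLD,
) -> DEGTable:
    """DEGs of one case profile against another (a.case / b.case).

    Both pairs must cover the same gene universe; the symmetric difference is
    reported otherwise.
    """
    if set(pair_a.genes) != set(pair_b.genes):
        diff = sorted(set(pair_a.genes) ^ set(pair_b.genes))
        raise InvalidInputError(
            f"gene universes differ; symmetric difference ({len(diff)} genes): {diff[:20]}"
        )
    index_b = {g: i for i, g in enumerate(pair_b.genes)}
    case_b = pair_b.case[[index_b[g] for g in pair_a.genes]]
    ratios = pair_a.case / case_b
    return call_degs(
        dict(zip(pair_a.genes, ratios.tolist())),
        threshold,
        labels=(pair_b.labels[1], pair_a.labels[1]),
    )


def read_expression_tsv(path: str | Path) -> ExpressionPair:
    """Read a TSV matrix with header; first column gene, next two intensities."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 3:
        raise InvalidInputError(
            f"expression matrix needs gene + two intensity columns, got {list(frame.columns)}"
        )
    gene_col, ctrl_col, case_col = frame.columns[:3]
    return ExpressionPair(
        genes=tuple(str(g) for g in frame[gene_col]),
        control=frame[ctrl_col].to_numpy(dtype=float),
        case=frame[case_col].to_numpy(dtype=float),
        labels=(str(ctrl_col), str(case_col)),
    )


def write_expression_tsv(pair: ExpressionPair, path: str | Path) -> None:
    pd.DataFrame(
        {"gene": pair.genes, pair.labels[0]: pair.control, pair.labels[1]: pair.case}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
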