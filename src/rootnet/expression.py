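"""Contrary-expression check: do targets accumulate where their sRNA does not?

A cleavage-competent sRNA represses its target, so across root anatomy the
target transcript should accumulate in the opposite pattern to the sRNA: a
target of a root-tip-enriched sRNA should be expressed higher in the whole
root than in the root tip, and vice versa.  The check uses a zone-labelled
expression matrix (eight root zones, replicated): the "root tip" mean pools
the root-cap and division-zone samples, the "whole root" mean pools ALL
samples (the whole root anatomically contains the tip), each as an
unweighted mean over samples after averaging nothing else — replicate means
fall out of the overall sample mean directly.

The oriented fold is mean_whole_root / mean_root_tip for a root-tip sRNA
and the reciprocal orientation for a whole-root sRNA; ``contrary`` is set
when fold >= ``min_fold`` (default 1.0: any contrary direction counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .degradome import ValidatedInteraction
from .io_core import ExpressionMatrix, strip_isoform_suffix

#: zones pooled into the "root tip" category
ROOT_TIP_ZONES = frozenset({"root_cap", "division_zone"})


@dataclass
class ExpressionContrast:
    gene_id: str
    mean_root_tip: float
    mean_whole_root: float
    fold: float
    srna_compartment: str  # compartment where the regulating sRNA is enriched
    contrary: bool
    missing: bool = False  # gene absent from the matrix


def _oriented_fold(mean_rt: float, mean_wr: float, srna_compartment: str) -> float:
    if srna_compartment == "root_tip":
        num, den = mean_wr, mean_rt
    elif srna_compartment == "whole_root":
        num, den = mean_rt, mean_wr
    else:
        raise ValueError(f"unknown sRNA compartment {srna_compartment!r}")
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def contrast_expression(
    matrix: ExpressionMatrix,
    interactions: Sequence[ValidatedInteraction] | Sequence[tuple[str, str]],
    srna_compartments: Mapping[str, str] | None = None,
    min_fold: float = 1.0,
    root_tip_zones: frozenset[str] = ROOT_TIP_ZONES,
) -> list[ExpressionContrast]:
    """Contrast target-gene expression against its sRNA's compartment.

    ``interactions`` is either a list of validated interactions (transcript
    ids mapped to genes by isoform-suffix stripping, sRNA compartments looked
    up in ``srna_compartments``) or a plain list of (gene_id, compartment)
    pairs.  One contrast is emitted per distinct (gene, compartment)
    combination; genes absent from the matrix are emitted with NaN means and
    ``missing=True`` and never counted as contrary.
    """
    pairs: set[tuple[str, str]] = set()
    for item in interactions:
        if isinstance(item, ValidatedInteraction):
            if srna_compartments is None:
                raise ValueError("srna_compartments required with ValidatedInteraction input")
            gene = strip_isoform_suffix(item.transcript_id)
            pairs.add((gene, srna_compartments[item.srna_id]))
        else:
            gene, compartment = item
            pairs.add((gene, compartment))

    tip_samples = matrix.samples_in_zones(root_tip_zones)
    if not tip_samples:
        raise ValueError(f"no samples labelled with root-tip zones {sorted(root_tip_zones)}")

    contrasts: list[ExpressionContrast] = []
    for gene, compartment in sorted(pairs):
        if gene not in matrix.values.index:
            contrasts.append(
                ExpressionContrast(gene, math.nan, math.nan, math.nan, compartment, False, True)
            )
            continue
        row = matrix.values.loc[gene]
        mean_rt = float(row[tip_samples].mean())
        mean_wr = float(row.mean())
        fold = _oriented_fold(mean_rt, mean_wr, compartment)
        contrary = bool(fold >= min_fold) if not math.isnan(fold) else False
        contrasts.append(ExpressionContrast(gene, mean_rt, mean_wr, fold, compartment, contrary))
    return contrasts


def write_contrasts(contrasts: Sequence[ExpressionContrast], path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tsrna_compartment\tmean_root_tip\tmean_whole_root\tfold\tcontrary\tmissing\n")
        for c in contrasts:
            handle.write(
                f"{c.gene_id}\t{c.srna_compartment}\t{c.mean_root_tip:.6g}\t"
                f"{c.mean_whole_root:.6g}\t{c.fold:.6g}\t{c.contrary}\t{c.missing}\n"
            )
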