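"""Cross-platform signature transfer through gene identifiers.

A signature derived on a discovery array is carried to a clinical array by
mapping its probesets to gene ids and collecting *every* destination
probeset of each mapped gene (no best-probeset collapsing). Probesets with
no gene annotation are dropped with a warning.
"""

from __future__ import annotations

import warnings
from typing import Sequence

from .datatypes import (CychypError, ExpressionMatrix, MappingReport,
                        ProbeAnnotation, Signature)


def map_signature(
    sig: Signature,
    annot_src: ProbeAnnotation,
    annot_dst: ProbeAnnotation,
) -> tuple[Signature, MappingReport]:
    """Map a signature to the destination platform via shared gene ids.

    The destination signature contains all destination probesets whose gene
    appears in the source signature's gene set, ordered by the source rank
    of the gene (best source probeset first) and then by destination
    probeset id. Returns the mapped signature and a cardinality report.
    """
    if sig.platform != annot_src.platform:
        raise CychypError(
            f"signature platform {sig.platform!r} does not match "
            f"annotation platform {annot_src.platform!r}")

    dropped = [p for p in sig.probeset_ids if p not in annot_src.probe_to_gene]
    if dropped:
        warnings.warn(f"{len(dropped)} signature probesets lack gene "
                      "annotation and were dropped")

    # source rank of each gene = rank of its best-ranked source probeset
    gene_rank: dict[str, int] = {}
    for rank, probe in enumerate(sig.probeset_ids):
        gene = annot_src.probe_to_gene.get(probe)
        if gene is not None and gene not in gene_rank:
            gene_rank[gene] = rank

    by_gene: dict[str, list[str]] = {}
    for probe, gene in annot_dst.probe_to_gene.items():
        if gene in gene_rank:
            by_gene.setdefault(gene, []).append(probe)

    ordered: list[str] = []
    for gene in sorted(by_gene, key=lambda g: gene_rank[g]):
        ordered.extend(sorted(by_gene[gene]))
    if not ordered:
        raise CychypError("empty mapping: annotations share no signature gene")

    report = MappingReport(
        n_source_probesets=sig.size,
        n_unique_genes=len(gene_rank),
        n_genes_on_destination=len(by_gene),
        n_destination_probesets=len(ordered),
        dropped=dropped,
    )
    return Signature(ordered, annot_dst.platform), report


def restrict_platform(
    expr: ExpressionMatrix,
    allowed_probesets: Sequence[str],
) -> ExpressionMatrix:
    """Restrict a matrix to probesets shared with another platform.

    Original row order is preserved; an empty intersection is an error.
    """
    if len(allowed_probesets) == 0:
        raise CychypError("allowed probeset list must be non-empty")
    allowed = set(allowed_probesets)
    keep = [p for p in expr.probeset_ids if p in allowed]
    if not keep:
        raise CychypError("no probesets in common with the allowed list")
    return ExpressionMatrix(expr.values.loc[keep], expr.platform)
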