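"""Surfaceome data-mining funnel.

Cross-references the quantified proteome with annotation flags to
produce the nested inventory: all quantified proteins -> membrane
proteins -> growth-factor receptors -> neurotrophic receptors. Counts
at each stage are logged and collected into the run report; they are
monotone non-increasing by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

from .io import AnnotationSet
from .quant import DifferentialRecord

logger = logging.getLogger("rlmatch")

__all__ = ["FunnelCounts", "filter_membrane", "classify_receptors", "run_funnel"]


@dataclass(frozen=True)
class FunnelCounts:
    """Protein counts surviving each annotation-funnel stage."""

    quantified: int
    membrane: int
    growth_factor_receptors: int
    neurotrophic_receptors: int
    unannotated: int

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def filter_membrane(
    records: Sequence[DifferentialRecord], ann: AnnotationSet
) -> list[DifferentialRecord]:
    """Keep records whose accession is annotated as a membrane protein.

    Accessions absent from the annotation set are excluded (and counted
    in the log); the funnel only trusts explicit membrane evidence.
    """
    membrane = ann.membrane_accessions()
    kept = [r for r in records if r.accession in membrane]
    logger.info(
        "membrane filter: %d of %d quantified proteins survive",
        len(kept),
        len(records),
    )
    return kept


def classify_receptors(
    records_membrane: Sequence[DifferentialRecord], ann: AnnotationSet
) -> tuple[list[DifferentialRecord], list[DifferentialRecord]]:
    """Split the membrane inventory into (growth-factor, neurotrophic) receptors.

    The neurotrophic subset is nested inside the growth-factor subset;
    the nesting is guaranteed by AnnotationSet's load-time invariant.
    """
    gf_accs = ann.growth_factor_receptor_accessions()
    nt_accs = ann.neurotrophic_receptor_accessions()
    gf = [r for r in records_membrane if r.accession in gf_accs]
    nt = [r for r in records_membrane if r.accession in nt_accs]
    logger.info(
        "receptor classification: %d growth-factor receptors, %d neurotrophic",
        len(gf),
        len(nt),
    )
    return gf, nt


def run_funnel(
    records: Sequence[DifferentialRecord], ann: AnnotationSet
) -> tuple[list[DifferentialRecord], list[DifferentialRecord], list[DifferentialRecord], FunnelCounts]:
    """Full funnel: membrane filter then receptor classification, with counts."""
    membrane = filter_membrane(records, ann)
    gf, nt = classify_receptors(membrane, ann)
    counts = FunnelCounts(
        quantified=len(records),
        membrane=len(membrane),
        growth_factor_receptors=len(gf),
        neurotrophic_receptors=len(nt),
        unannotated=sum(1 for r in records if r.accession not in ann),
    )
    return membrane, gf, nt, counts
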