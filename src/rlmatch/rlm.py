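"""Receptor-ligand matching (RLM).

The selection-and-matching step: neurotrophic receptors enriched in the
differentiated state beyond a fold threshold (>= 10-fold by default) and
quantifiable there are joined against the receptor->ligand
knowledgebase, yielding a ranked medium-supplementation recommendation.
Selection is fold-based; the p-value is reported but not filtered on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import Condition, DataError, LigandKBEntry, UNMATCHED
from .quant import DifferentialRecord

logger = logging.getLogger("rlmatch")

__all__ = [
    "RLMParams",
    "RLMRecommendation",
    "select_enriched_receptors",
    "match_ligands",
    "compare_supplement_sets",
    "recommendation_markdown",
]


@dataclass(frozen=True)
class RLMParams:
    """Tunable rules of the receptor-selection step.

    ``fold_threshold`` is the minimum B/A ratio (default 10, the
    ">=10-fold enriched" rule); ``require_quantifiable_in_B`` drops
    receptors not reliably detected in the differentiated state;
    ``require_ligand_available`` additionally gates the supplementation
    flag on commercial ligand availability (off by default so the full
    candidate table stays visible).
    """

    fold_threshold: float = 10.0
    direction: str = "enriched_in_B"
    require_quantifiable_in_B: bool = True
    require_ligand_available: bool = False

    def __post_init__(self) -> None:
        if not self.fold_threshold > 0:
            raise DataError("fold_threshold must be positive")
        if self.direction != "enriched_in_B":
            raise DataError(f"unsupported direction {self.direction!r}")


@dataclass(frozen=True)
class RLMRecommendation:
    """One receptor->ligand row of the ranked supplementation table."""

    rank: int
    receptor_symbol: str
    receptor_accession: str
    ligand_name: str
    log2_ratio: float
    p_value: float
    selected_for_supplementation: bool
    rationale_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise DataError("rank must be a positive integer")

    @staticmethod
    def field_order() -> tuple[str, ...]:
        return (
            "rank",
            "receptor_symbol",
            "receptor_accession",
            "ligand_name",
            "log2_ratio",
            "p_value",
            "selected_for_supplementation",
            "rationale_flags",
        )


def select_enriched_receptors(
    neurotrophic_records: Sequence[DifferentialRecord],
    params: RLMParams = RLMParams(),
) -> list[DifferentialRecord]:
    """Receptors enriched in state B beyond the fold threshold.

    Candidates must have ``ratio_B_over_A >= fold_threshold`` and, when
    required, be quantifiable in condition B. Output order is
    deterministic: descending log2 ratio, ties by ascending p-value,
    then lexicographic accession.
    """
    candidates = [
        r
        for r in neurotrophic_records
        if r.ratio_B_over_A >= params.fold_threshold
        and (not params.require_quantifiable_in_B or r.quantifiable_in(Condition.B))
    ]
    candidates.sort(key=lambda r: (-r.log2_ratio, r.p_value, r.accession))
    logger.info(
        "receptor selection: %d of %d neurotrophic receptors pass the "
        ">=%g-fold rule",
        len(candidates),
        len(neurotrophic_records),
        params.fold_threshold,
    )
    return candidates


def match_ligands(
    candidates: Sequence[DifferentialRecord],
    kb: Sequence[LigandKBEntry],
    params: RLMParams = RLMParams(),
) -> list[RLMRecommendation]:
    """Join selected receptors to their knowledgebase ligands.

    Each candidate contributes one row per matching KB entry (matched by
    accession when the KB provides one, else by symbol, case-insensitive);
    candidates without any KB entry are emitted with the unmatched
    sentinel and ``selected_for_supplementation=False``. Ranks run 1..k
    without gaps in candidate order (ties within a receptor ordered by
    ligand name).
    """
    recs: list[RLMRecommendation] = []
    rank = 0
    for cand in candidates:
        matches = [
            e
            for e in kb
            if (e.receptor_accession and e.receptor_accession == cand.accession)
            or e.receptor_symbol.upper() == cand.gene_symbol.upper()
        ]
        matches.sort(key=lambda e: e.ligand_name)
        base_flags = {"fold_pass"}
        if cand.quantifiable_in(Condition.B):
            base_flags.add("detected_B")
        if not matches:
            rank += 1
            recs.append(
                RLMRecommendation(
                    rank=rank,
                    receptor_symbol=cand.gene_symbol,
                    receptor_accession=cand.accession,
                    ligand_name=UNMATCHED,
                    log2_ratio=cand.log2_ratio,
                    p_value=cand.p_value,
                    selected_for_supplementation=False,
                    rationale_flags=frozenset(base_flags),
                )
            )
            continue
        for entry in matches:
            flags = set(base_flags) | {"kb_match"}
            if entry.ligand_available:
                flags.add("ligand_available")
            selected = (
                "fold_pass" in flags
                and (not params.require_quantifiable_in_B or "detected_B" in flags)
                and (not params.require_ligand_available or "ligand_available" in flags)
            )
            rank += 1
            recs.append(
                RLMRecommendation(
                    rank=rank,
                    receptor_symbol=cand.gene_symbol,
                    receptor_accession=cand.accession,
                    ligand_name=entry.ligand_name,
                    log2_ratio=cand.log2_ratio,
                    p_value=cand.p_value,
                    selected_for_supplementation=selected,
                    rationale_flags=frozenset(flags),
                )
            )
    return recs


def compare_supplement_sets(
    rec_set_a: Iterable[str], rec_set_b: Iterable[str]
) -> dict[str, list[str]]:
    """Structured diff of two ligand supplement sets (A relative to B).

    ``added`` are ligands in A but not B, ``removed`` in B but not A,
    ``shared`` in both — e.g. the RLM-selected set against the
    conventional {BDNF, NT3} supplement.
    """
    a, b = set(rec_set_a), set(rec_set_b)
    return {
        "shared": sorted(a & b),
        "added": sorted(a - b),
        "removed": sorted(b - a),
    }


def recommendation_markdown(recs: Sequence[RLMRecommendation]) -> str:
    """Human-readable supplementation table (selected rows starred)."""
    lines = [
        "| rank | receptor | accession | ligand | log2(B/A) | p | selected |",
        "|---:|---|---|---|---:|---:|:---:|",
    ]
    for r in sorted(recs, key=lambda x: x.rank):
        star = "*" if r.selected_for_supplementation else ""
        lines.append(
            f"| {r.rank} | {r.receptor_symbol} | {r.receptor_accession} | "
            f"{r.ligand_name} | {r.log2_ratio:.2f} | {r.p_value:.3g} | {star} |"
        )
    return "\n".join(lines) + "\n"
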