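"""Receptor selection, ligand matching and supplement-set comparison."""

import math

import numpy as np
import pytest

from rlmatch.io import DataError, LigandKBEntry, UNMATCHED, default_ligand_kb
from rlmatch.quant import DetectionClass, DifferentialRecord
from rlmatch.rlm import (
    RLMParams,
    compare_supplement_sets,
    match_ligands,
    recommendation_markdown,
    select_enriched_receptors,
)


def receptor_record(symbol, accession, ratio, p=0.01, detection=DetectionClass.both):
    return DifferentialRecord(
        accession=accession,
        gene_symbol=symbol,
        mean_norm_intensity_A=1e-6,
        mean_norm_intensity_B=1e-6 * ratio,
        ratio_B_over_A=ratio,
        log2_ratio=math.log2(ratio),
        p_value=p,
        n_detected_A=3 if detection in (DetectionClass.both, DetectionClass.A_only) else 0,
        n_detected_B=3 if detection in (DetectionClass.both, DetectionClass.B_only) else 0,
        detection_class=detection,
    )


def random_records(rng, n=25):
    return [
        receptor_record(
            f"R{i}",
            f"Q{i:05d}",
            ratio=float(10 ** rng.uniform(-2, 2.5)),
            p=float(rng.uniform(0, 1)),
            detection=rng.choice(
                [DetectionClass.both, DetectionClass.B_only, DetectionClass.A_only]
            ),
        )
        for i in range(n)
    ]


class TestSelection:
    def test_infinite_threshold_empty(self, rng):
        recs = random_records(rng)
        assert select_enriched_receptors(recs, RLMParams(fold_threshold=math.inf)) == []

    def test_wrong_direction_and_undetectable_excluded(self):
        recs = [
            receptor_record("FGFR1", "P11362", ratio=0.05),
            receptor_record("NTRK2", "Q16620", ratio=15.0),
            receptor_record("GFRA1", "P56159", ratio=20.0, detection=DetectionClass.A_only),
        ]
        selected = {r.gene_symbol for r in select_enriched_receptors(recs, RLMParams())}
        assert selected == {"NTRK2"}  # FGFR1 wrong direction, GFRA1 not quantifiable in B

    def test_threshold_monotonicity(self, rng):
        for _ in range(50):
            recs = random_records(rng, n=int(rng.integers(0, 40)))
            at10 = {r.accession for r in select_enriched_receptors(recs, RLMParams(10))}
            at20 = {r.accession for r in select_enriched_receptors(recs, RLMParams(20))}
            assert at20 <= at10

    def test_order_deterministic_under_permutation(self, rng):
        recs = random_records(rng)
        perm = list(recs)
        rng.shuffle(perm)
        a = [r.accession for r in select_enriched_receptors(recs, RLMParams(2))]
        b = [r.accession for r in select_enriched_receptors(perm, RLMParams(2))]
        assert a == b
        # ordering: descending log2 ratio, ties by p then accession
        chosen = select_enriched_receptors(recs, RLMParams(2))
        keys = [(-r.log2_ratio, r.p_value, r.accession) for r in chosen]
        assert keys == sorted(keys)

    def test_invalid_fold_threshold(self):
        with pytest.raises(DataError, match="fold_threshold"):
            RLMParams(fold_threshold=0)


class TestMatchLigands:
    def test_study_candidates_map_to_star_ligands(self):
        cands = [
            receptor_record("NTRK2", "Q16620", 15.0),
            receptor_record("CNTFR", "P26992", 14.0),
            receptor_record("GFRA1", "P56159", 13.0),
            receptor_record("GFRA2", "O00451", 12.0),
            receptor_record("GFRA3", "O60609", 11.0),
        ]
        recs = match_ligands(cands, default_ligand_kb(), RLMParams())
        selected = {r.ligand_name for r in recs if r.selected_for_supplementation}
        assert selected == {"BDNF", "CNTF", "GDNF", "NRTN", "PSPN"}

    def test_unmatched_candidate_sentinel_row(self):
        cands = [receptor_record("NOVEL1", "X99999", 30.0)]
        recs = match_ligands(cands, default_ligand_kb(), RLMParams())
        assert len(recs) == 1
        assert recs[0].ligand_name == UNMATCHED
        assert not recs[0].selected_for_supplementation

    def test_equals_nested_loop_join_oracle(self, rng):
        cands = select_enriched_receptors(random_records(rng), RLMParams(2))
        kb = [
            LigandKBEntry(f"R{i}", f"Q{i:05d}", f"LIG{i}-{j}", bool(rng.integers(2)))
            for i in range(0, 25, 2)
            for j in range(int(rng.integers(1, 3)))
        ]
        recs = match_ligands(cands, kb, RLMParams())
        oracle = []
        for c in cands:
            hits = sorted(
                (e.ligand_name for e in kb if e.receptor_symbol == c.gene_symbol)
            )
            oracle.extend((c.accession, lig) for lig in (hits or [UNMATCHED]))
        assert [(r.receptor_accession, r.ligand_name) for r in recs] == oracle

    def test_ranks_contiguous_from_one(self, rng):
        cands = select_enriched_receptors(random_records(rng), RLMParams(2))
        kb = [LigandKBEntry(c.gene_symbol, c.accession, f"L-{c.gene_symbol}") for c in cands[::2]]
        recs = match_ligands(cands, kb, RLMParams())
        assert [r.rank for r in recs] == list(range(1, len(recs) + 1))

    def test_availability_gate(self):
        cands = [receptor_record("LIFR", "P42702", 20.0)]
        kb = [LigandKBEntry("LIFR", "P42702", "LIF", ligand_available=False)]
        open_recs = match_ligands(cands, kb, RLMParams())
        gated = match_ligands(cands, kb, RLMParams(require_ligand_available=True))
        assert open_recs[0].selected_for_supplementation
        assert not gated[0].selected_for_supplementation
        assert "ligand_available" not in gated[0].rationale_flags

    def test_markdown_table_stars_selected(self):
        cands = [receptor_record("NTRK2", "Q16620", 15.0)]
        recs = match_ligands(cands, default_ligand_kb(), RLMParams())
        md = recommendation_markdown(recs)
        assert "| NTRK2 |" in md and "BDNF" in md


class TestCompareSupplementSets:
    def test_rlm_vs_conventional(self):
        diff = compare_supplement_sets(
            {"BDNF", "CNTF", "GDNF", "NRTN", "PSPN"}, {"BDNF", "NT3"}
        )
        assert diff == {
            "shared": ["BDNF"],
            "added": ["CNTF", "GDNF", "NRTN", "PSPN"],
            "removed": ["NT3"],
        }

    def test_identical_sets_empty_diff(self):
        diff = compare_supplement_sets({"BDNF"}, {"BDNF"})
        assert diff["added"] == [] and diff["removed"] == [] and diff["shared"] == ["BDNF"]

    def test_disjoint_sets(self):
        diff = compare_supplement_sets({"A", "B"}, {"C", "D", "E"})
        assert len(diff["added"]) == 2 and len(diff["removed"]) == 3 and diff["shared"] == []
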