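"""Enrichment, contaminant-exclusion and GWAS filters."""

import math

import numpy as np
import pytest

from podoscreen.errors import ConfigurationError, ParameterError, ValidationError
from podoscreen.filters import (
    GwasCatalog,
    compartment_enrichment,
    contaminant_exclusion,
    enrichment_records,
    filter_by_enrichment,
    gwas_crossref,
)
from podoscreen.genes import GeneId
from podoscreen.screen import MarkerPanel, build_candidate_table, correlate_bait

from conftest import make_matrix


def _basic_matrix():
    # 3 cortex + 2 medulla samples; cortex values vary (correlatable baits)
    # but have hand-set means: 3, 5, 1, 0
    vals = np.array(
        [
            [2.0, 3.0, 4.0, 2.0, 2.0],   # fold 1.5
            [4.0, 5.0, 6.0, 0.0, 0.0],   # fold inf
            [0.5, 1.0, 1.5, 1.0, 1.0],   # fold 1.0
            [0.0, 0.0, 0.0, 0.0, 0.0],   # undefined
        ]
    )
    return make_matrix(vals, compartment=["cortex"] * 3 + ["medulla"] * 2)


class TestEnrichment:
    def test_fold_arithmetic(self):
        m = _basic_matrix()
        rec = compartment_enrichment(m, m.genes[0])
        assert rec.cortex_mean_tpm == 3.0
        assert rec.medulla_mean_tpm == 2.0
        assert rec.fold == pytest.approx(1.5)

    def test_zero_medulla_gives_infinite_fold(self):
        m = _basic_matrix()
        rec = compartment_enrichment(m, m.genes[1])
        assert rec.fold == math.inf and not rec.undefined

    def test_both_zero_flags_undefined(self):
        m = _basic_matrix()
        rec = compartment_enrichment(m, m.genes[3])
        assert rec.undefined and math.isnan(rec.fold)

    def test_requires_medulla_samples(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(ConfigurationError):
            compartment_enrichment(m, m.genes[0])

    def test_matches_brute_force_means(self, small_sim):
        matrix, _ = small_sim
        recs = enrichment_records(matrix)
        rng = np.random.default_rng(0)
        cortex = [j for j, c in enumerate(matrix.compartment) if c == "cortex"]
        medulla = [j for j, c in enumerate(matrix.compartment) if c == "medulla"]
        for i in rng.choice(matrix.n_genes(), 25, replace=False):
            c = sum(matrix.tpm[i, j] for j in cortex) / len(cortex)
            m_ = sum(matrix.tpm[i, j] for j in medulla) / len(medulla)
            rec = recs[matrix.genes[i].key]
            assert rec.fold == pytest.approx(c / m_, abs=1e-12, rel=1e-12)

    def test_pseudocount_gives_finite_fold(self):
        m = _basic_matrix()
        rec = compartment_enrichment(m, m.genes[1], pseudocount=1.0)
        assert rec.fold == pytest.approx(6.0)


def _screened_table(matrix):
    profiles = {
        matrix.genes[i].key: correlate_bait(matrix, matrix.genes[i])
        for i in range(2)
    }
    return build_candidate_table(matrix, profiles, 1.0)


class TestEnrichmentFilter:
    def test_boundary_passes_at_threshold(self):
        m = _basic_matrix()
        table = filter_by_enrichment(_screened_table(m), 1.5, enrichment_records(m))
        passes = table.df["passes_enrichment"]
        assert passes.iloc[0] == True  # fold exactly 1.5 passes (>= convention)
        assert passes.iloc[1] == True  # inf passes any finite threshold
        assert passes.iloc[2] == False  # fold 1.0 fails at 1.5
        assert passes.iloc[3] == False  # undefined (0/0) fails

    def test_failing_candidates_are_retained_not_dropped(self):
        m = _basic_matrix()
        table = filter_by_enrichment(_screened_table(m), 1.5, enrichment_records(m))
        assert len(table.df) == 4

    def test_missing_record_for_candidate_raises(self):
        m = _basic_matrix()
        with pytest.raises(ValidationError, match="ENSG"):
            filter_by_enrichment(_screened_table(m), 1.5, {})

    def test_pass_count_monotone_in_threshold(self, small_sim):
        matrix, _ = small_sim
        table = _screened_table(matrix)
        recs = enrichment_records(matrix)
        counts = []
        for thr in (1.0, 1.5, 2.0, 5.0):
            t = filter_by_enrichment(table, thr, recs)
            counts.append(int((t.candidates()["passes_enrichment"] == True).sum()))
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # thresholds actually bite


class TestContaminantExclusion:
    def _matrix_with_planted_copy(self):
        """Candidate 'COPY' is an exact duplicate of the mesangial marker."""
        rng = np.random.default_rng(8)
        pdgfrb = rng.lognormal(2, 0.7, 30)
        pecam1 = rng.lognormal(2, 0.7, 30)
        abo = rng.lognormal(2, 0.7, 30)
        bait = rng.lognormal(2, 0.7, 30)
        others = rng.lognormal(2, 0.7, (16, 30))
        vals = np.vstack([bait, bait * 1.7, pdgfrb.copy(), pdgfrb, pecam1, abo, others])
        keys = (
            ["ENSG00000161270", "ENSG00000116218", "ENSG70000000001",
             "ENSG00000113721", "ENSG00000261371", "ENSG00000175164"]
            + [f"ENSG{80000000000 + i:011d}" for i in range(16)]
        )
        m = make_matrix(vals, keys=keys)
        panel = MarkerPanel(
            baits=(GeneId("ENSG00000161270"), GeneId("ENSG00000116218")),
        )
        profiles = {
            b.key: correlate_bait(m, b) for b in panel.baits
        }
        return m, build_candidate_table(m, profiles, 1.0), panel

    def test_perfect_copy_of_marker_is_excluded_as_mesangial(self):
        m, table, panel = self._matrix_with_planted_copy()
        out = contaminant_exclusion(m, table, panel, q_neg=0.1)
        # top 10% of 22 genes = 2: the marker itself plus its exact copy
        assert out.df.at["ENSG70000000001", "excluded_by"] == "mesangial"

    def test_unrelated_candidate_not_excluded(self):
        m, table, panel = self._matrix_with_planted_copy()
        # q_neg so small each top list holds only the contaminant marker itself
        out = contaminant_exclusion(m, table, panel, q_neg=0.01)
        assert out.df.at["ENSG00000161270", "excluded_by"] == ""
        assert out.df.at["ENSG70000000001", "excluded_by"] == ""

    def test_excluded_candidate_is_in_that_top_list(self):
        from podoscreen.screen import top_fraction

        m, table, panel = self._matrix_with_planted_copy()
        out = contaminant_exclusion(m, table, panel, q_neg=0.1)
        prof = correlate_bait(m, panel.contaminants["mesangial"])
        top = {g.key for g in top_fraction(prof, 0.1, m.n_genes())}
        excluded = out.df.index[out.df["excluded_by"].str.contains("mesangial")]
        assert set(excluded) <= top

    def test_exclusion_count_monotone_in_q_neg(self, small_sim):
        matrix, _ = small_sim
        table = _screened_table(matrix)
        panel = MarkerPanel()
        counts = []
        for q in (0.05, 0.01, 0.001):
            out = contaminant_exclusion(matrix, table, panel, q_neg=q)
            counts.append(int((out.df["excluded_by"] != "").sum()))
        assert counts == sorted(counts, reverse=True)

    def test_q_neg_out_of_range(self, small_sim):
        matrix, _ = small_sim
        with pytest.raises(ParameterError):
            contaminant_exclusion(matrix, _screened_table(matrix), MarkerPanel(), 0.0)


class TestFilterComposition:
    def test_order_independence(self, small_sim):
        matrix, _ = small_sim
        table = _screened_table(matrix)
        panel = MarkerPanel()
        recs = enrichment_records(matrix)
        a = contaminant_exclusion(
            matrix, filter_by_enrichment(table, 1.5, recs), panel, 0.01
        )
        b = filter_by_enrichment(
            contaminant_exclusion(matrix, table, panel, 0.01), 1.5, recs
        )
        assert a.df["passes_enrichment"].equals(b.df["passes_enrichment"])
        assert a.df["excluded_by"].equals(b.df["excluded_by"])
        assert a.survivors() == b.survivors()


class TestGwasCrossref:
    def _table(self):
        vals = np.abs(np.random.default_rng(3).lognormal(1, 0.5, (5, 12)))
        m = make_matrix(
            vals,
            keys=[f"ENSG{81000000000 + i:011d}" for i in range(5)],
            symbols=["ARMH4", "WIPF3", "MYL3", "MAPT", "OTHER"],
        )
        return _screened_table(m)

    def test_trait_overlaps(self):
        """Albuminuria hits MYL3+WIPF3; lupus nephritis hits ARMH4; MAPT none."""
        table = self._table()
        catalogs = [
            GwasCatalog.from_symbols("albuminuria", ["MYL3", "WIPF3"]),
            GwasCatalog.from_symbols("lupus_nephritis", ["ARMH4"]),
        ]
        out = gwas_crossref(table, catalogs)
        traits = dict(zip(out.df["symbol"], out.df["gwas_traits"]))
        assert traits["WIPF3"] == "albuminuria"
        assert traits["MYL3"] == "albuminuria"
        assert traits["ARMH4"] == "lupus_nephritis"
        assert traits["MAPT"] == ""

    def test_empty_catalog_list_leaves_all_unannotated(self):
        out = gwas_crossref(self._table(), [])
        assert (out.df["gwas_traits"] == "").all()

    def test_candidate_in_two_catalogs_gets_both(self):
        table = self._table()
        catalogs = [
            GwasCatalog.from_symbols("albuminuria", ["wipf3"]),  # case-insensitive
            GwasCatalog.from_symbols("lupus_nephritis", ["WIPF3"]),
        ]
        out = gwas_crossref(table, catalogs)
        traits = dict(zip(out.df["symbol"], out.df["gwas_traits"]))
        assert traits["WIPF3"] == "albuminuria;lupus_nephritis"

    def test_matching_by_ensembl_id(self):
        table = self._table()
        catalogs = [GwasCatalog.from_symbols("albuminuria", ["ENSG81000000003"])]
        out = gwas_crossref(table, catalogs)
        traits = dict(zip(out.df["symbol"], out.df["gwas_traits"]))
        assert traits["MAPT"] == "albuminuria"

    def test_catalog_from_file(self, tmp_path):
        p = tmp_path / "albuminuria.txt"
        p.write_text("MYL3\nWIPF3\n\n")
        cat = GwasCatalog.from_file("albuminuria", p)
        assert "WIPF3" in cat.genes and len(cat.genes) == 2
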