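import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import brute_force_local_score

from myelotrace.homology import (AlignmentResult, HomologyCriteria,
                                 ScoringScheme, aggregate_by_group,
                                 call_homology, evalue, local_align,
                                 read_panel_fasta, score_species_panel,
                                 write_panel_fasta)
from myelotrace.synthetic import (SimulationConfig, evolve_protein_family,
                                  random_protein, simulate_species_set,
                                  stage_rng)

AA = "ACDEFGHIKLMNPQRSTVWY"


def result(coverage=1.0, e=0.0, qlen=100):
    span = (0, int(round(coverage * qlen)))
    return AlignmentResult(score=200, query_span=span, subject_span=span,
                           alignment_length=span[1], aligned_pairs=span[1],
                           identities=span[1], positives=span[1],
                           query_length=qlen, subject_length=qlen, evalue=e)


class TestLocalAlign:
    def test_self_alignment_is_perfect(self):
        seq = "MKVLITGAGSGIGLE"
        r = local_align(seq, seq)
        assert r.identities == len(seq)
        assert r.percent_identity == 100.0
        assert r.query_coverage == 1.0
        assert r.query_span == (0, len(seq))

    def test_classic_toy_pair_matches_oracle(self):
        q, s = "HEAGAWGHEE", "PAWHEAE"
        assert local_align(q, s).score == brute_force_local_score(q, s)

    def test_matches_bruteforce_on_short_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            lq, ls = rng.integers(1, 9, size=2)
            q = "".join(rng.choice(list(AA), lq))
            s = "".join(rng.choice(list(AA), ls))
            assert local_align(q, s).score == brute_force_local_score(q, s)

    def test_score_never_negative_and_empty_hit_handled(self):
        r = local_align("W", "P")  # BLOSUM62 W/P = -4
        assert r.score == 0
        assert r.alignment_length == 0 and r.query_coverage == 0.0

    def test_invalid_residue_named_with_position(self):
        with pytest.raises(ValueError, match="position 2 of query"):
            local_align("MKZLL", "MKVLL")
        with pytest.raises(ValueError, match="empty"):
            local_align("", "MKVL")

    def test_ambiguity_code_scores_zero(self):
        r = local_align("MKVXLA", "MKVWLA")
        assert r.aligned_pairs == 6
        assert r.identities == 5  # X does not count as an identity

    def test_identity_symmetric_for_ungapped_identical_hits(self):
        q, s = "MKVLITGAGS", "MKVLITGAGS"
        a, b = local_align(q, s), local_align(s, q)
        assert a.percent_identity == b.percent_identity == 100.0

    def test_blastp_agrees_on_raw_score(self, tmp_path):
        """Cross-check against the standard search tool, heuristics disabled
        where possible (no compositional adjustment, no masking)."""
        if shutil.which("blastp") is None:
            pytest.skip("blastp not on PATH")
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list(AA), 150))
        mut = list(base)
        for _ in range(35):
            mut[int(rng.integers(len(mut)))] = AA[int(rng.integers(20))]
        mut = "".join(mut)
        (tmp_path / "q.fa").write_text(f">q\n{base}\n")
        (tmp_path / "s.fa").write_text(f">s\n{mut}\n")
        out = subprocess.run(
            ["blastp", "-query", str(tmp_path / "q.fa"),
             "-subject", str(tmp_path / "s.fa"), "-comp_based_stats", "0",
             "-seg", "no", "-outfmt", "6 score length nident"],
            capture_output=True, text=True, check=True)
        score, length, nident = map(int, out.stdout.split()[:3])
        r = local_align(base, mut)
        assert r.score == score
        assert (r.alignment_length, r.identities) == (length, nident)


class TestEvalue:
    def test_closed_form(self):
        scheme = ScoringScheme()
        e = evalue(50, 100, 100, scheme)
        assert e == pytest.approx(0.041 * 100 * 100 * math.exp(-0.267 * 50))

    def test_strictly_decreasing_in_score(self):
        scheme = ScoringScheme()
        es = [evalue(s, 200, 300, scheme) for s in range(0, 500, 7)]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert es[-1] < 1e-50  # E -> 0 as S grows

    def test_linear_in_search_space(self):
        scheme = ScoringScheme()
        assert evalue(80, 200, 100, scheme) == \
            pytest.approx(2 * evalue(80, 100, 100, scheme))

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, ScoringScheme())


class TestHomologyCall:
    def test_low_coverage_rejected_despite_good_evalue(self):
        call = call_homology(result(coverage=0.39, e=1e-30))
        assert not call.is_homolog and call.reason == "low_coverage"

    def test_high_evalue_rejected_despite_good_coverage(self):
        call = call_homology(result(coverage=0.5, e=1e-10))
        assert not call.is_homolog and call.reason == "high_evalue"

    def test_both_failures_reported(self):
        call = call_homology(result(coverage=0.1, e=1.0))
        assert call.reason == "both"

    def test_perfect_hit_accepted(self):
        call = call_homology(result(coverage=1.0, e=0.0))
        assert call.is_homolog and call.reason == "ok"

    @given(st.floats(min_value=0.01, max_value=1.0),
           st.floats(min_value=1e-60, max_value=1.0))
    def test_permissive_criteria_accept_everything(self, cov, e):
        criteria = HomologyCriteria(min_query_coverage=1e-12,
                                    max_evalue=math.inf)
        assert call_homology(result(coverage=cov, e=e), criteria).is_homolog

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_in_coverage(self, cov_lo, cov_hi):
        cov_lo, cov_hi = sorted((cov_lo, cov_hi))
        lo = call_homology(result(coverage=cov_lo, e=1e-30))
        hi = call_homology(result(coverage=cov_hi, e=1e-30))
        assert not (lo.is_homolog and not hi.is_homolog)


class TestPanel:
    def test_reference_scores_100_against_itself(self):
        seq = random_protein(120, stage_rng(0, "q"))
        table = score_species_panel(seq, {"human": seq})
        row = table.iloc[0]
        assert row["percent_identity"] == 100.0 and row["homolog"]

    def test_zero_divergence_panel_all_100(self):
        cfg = SimulationConfig(seed=3, species_per_group=1,
                               substitution_rate=0.0, indel_rate=0.0,
                               gene_loss_rate=0.0)
        root = random_protein(100, stage_rng(3, "root"))
        _, newick = simulate_species_set(cfg)
        seqs, _ = evolve_protein_family(root, newick, cfg)
        table = score_species_panel(root, seqs)
        assert (table["percent_identity"] == 100.0).all()

    def test_identity_rank_matches_inverse_divergence(self):
        from scipy import stats
        cfg = SimulationConfig(seed=5, species_per_group=1, indel_rate=0.0,
                               gene_loss_rate=0.0)
        root = random_protein(150, stage_rng(5, "root"))
        _, newick = simulate_species_set(cfg)
        seqs, truth = evolve_protein_family(root, newick, cfg)
        table = score_species_panel(root, seqs).set_index("species")
        species = list(truth.divergence)
        rho = stats.spearmanr(
            [truth.divergence[sp] for sp in species],
            [table.loc[sp, "percent_identity"] for sp in species]).statistic
        assert rho < -0.5

    def test_absent_species_marked_missing(self):
        seq = random_protein(80, stage_rng(1, "q"))
        table = score_species_panel(seq, {"a": seq, "b": None})
        assert table.set_index("species").loc["b", "reason"] == "missing"
        with pytest.raises(ValueError, match="empty"):
            score_species_panel(seq, {})


class TestAggregate:
    def make_table(self, values, homolog=None):
        n = len(values)
        return pd.DataFrame({
            "species": [f"sp{i}" for i in range(n)],
            "protein": "CSF1R",
            "percent_identity": values,
            "homolog": homolog or [True] * n,
            "missing": False})

    def test_mean_min_max(self):
        table = self.make_table([80.0, 90.0])
        out = aggregate_by_group(table, {"sp0": "aves", "sp1": "aves"})
        row = out.iloc[0]
        assert (row["mean_pct"], row["min_pct"], row["max_pct"]) == \
            (85.0, 80.0, 90.0)
        assert row["n_species"] == 2

    def test_singleton_collapses(self):
        out = aggregate_by_group(self.make_table([70.0]), {"sp0": "aves"})
        row = out.iloc[0]
        assert row["mean_pct"] == row["min_pct"] == row["max_pct"] == 70.0
        assert row["sd_pct"] == 0.0

    def test_failed_hits_excluded_from_n(self):
        table = self.make_table([80.0, 20.0], homolog=[True, False])
        out = aggregate_by_group(table, {"sp0": "aves", "sp1": "aves"})
        assert out.iloc[0]["n_species"] == 1
        assert out.iloc[0]["mean_pct"] == 80.0

    def test_unmapped_species_rejected(self):
        with pytest.raises(ValueError, match="without a group"):
            aggregate_by_group(self.make_table([50.0]), {})


def test_panel_fasta_round_trip(tmp_path):
    seqs = {"sp1": "MKVLITGA", "sp2": "MKVLITGG", "sp3": None}
    grouping = {"sp1": "aves", "sp2": "aves", "sp3": "aves"}
    path = tmp_path / "panel.fa"
    write_panel_fasta(path, seqs, grouping, "CSF3")
    back, groups, protein = read_panel_fasta(path)
    assert back == {"sp1": "MKVLITGA", "sp2": "MKVLITGG"}
    assert groups == {"sp1": "aves", "sp2": "aves"}
    assert protein == "CSF3"
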