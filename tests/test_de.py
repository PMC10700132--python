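"""Differential expression, signature scoring, state gating, enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as ss

from perturbmap.assignment import GuideAssignment
from perturbmap.core_stats import CountMatrix, NormalizedMatrix, log_normalize
from perturbmap.de import (
    MarkerConfig,
    cluster_markers,
    gate_states,
    geneset_fisher,
    perturbation_de,
    read_gmt,
    signature_score,
)
from perturbmap.synthetic import StateSpec, make_modular_truth, simulate_screen
from perturbmap.fixtures import build_library_manifest
from perturbmap.synthetic import CaptureNoise


def _singlet_assignment(counts: dict[str, int]) -> GuideAssignment:
    rows, i = [], 0
    for target, n in counts.items():
        for _ in range(n):
            rows.append((f"c{i}", "singlet", target, "", "", ""))
            i += 1
    return GuideAssignment(
        pd.DataFrame(
            rows,
            columns=["cell_id", "status", "target", "construct_id", "guides", "umis"],
        ).set_index("cell_id")
    )


def _norm_from(dense: np.ndarray, genes) -> NormalizedMatrix:
    cm = CountMatrix(
        sp.csr_matrix(dense), [f"c{i}" for i in range(len(dense))], list(genes)
    )
    return log_normalize(cm)


class TestPerturbationDE:
    def test_below_min_cells_excluded_with_flag(self):
        a = _singlet_assignment({"X": 47, "NTC": 100})
        rng = np.random.default_rng(0)
        norm = _norm_from(rng.poisson(5, size=(147, 10)), [f"g{j}" for j in range(10)])
        dt = perturbation_de(norm, a, "X", min_cells=48)
        assert dt.excluded
        assert dt.table.empty
        assert "47" in dt.exclusion_reason

    def test_planted_effect_recovered_within_band(self, recovery_screens):
        """A planted ±0.8 log2 effect is estimated within ±0.15 at ≥500
        cells per side."""
        run = recovery_screens["planted"]
        de = run["de"]
        assert not de.excluded
        assert de.table["n_group1"].iloc[0] >= 500
        truth = run["truth"]
        up = truth.gene_programmes["A"]
        down = truth.gene_programmes["B"]
        assert de.table.loc[up, "log2_fc"].mean() == pytest.approx(0.8, abs=0.15)
        assert de.table.loc[down, "log2_fc"].mean() == pytest.approx(-0.8, abs=0.15)
        # significance concentrates on the perturbed programmes
        hits = de.significant()
        assert set(hits.index) <= set(up) | set(down)
        assert len(hits) > len(up)

    def test_null_type_i_error_controlled(self, recovery_screens):
        """Under a zero-effect simulation the FDR<0.05 discovery fraction
        stays at or below 0.05."""
        de = recovery_screens["null"]["de"]
        assert (de.table["fdr"] < 0.05).mean() <= 0.05

    def test_no_ntc_cells_raises(self):
        a = _singlet_assignment({"X": 60})
        norm = _norm_from(np.ones((60, 4)), list("abcd"))
        with pytest.raises(ValueError, match="NTC"):
            perturbation_de(norm, a, "X")


class TestClusterMarkers:
    def test_two_cluster_antisymmetry(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, size=(80, 12)).astype(float)
        counts[:40, 0] += 12  # gene g0 marks cluster A
        norm = _norm_from(counts, [f"g{j}" for j in range(12)])
        labels = pd.Series(
            ["A"] * 40 + ["B"] * 40, index=[f"c{i}" for i in range(80)]
        )
        tables = cluster_markers(norm, labels)
        ta, tb = tables["A"].table, tables["B"].table
        assert ta["log2_fc"].idxmax() == "g0"
        assert tb["log2_fc"].idxmin() == "g0"
        assert np.allclose(ta["log2_fc"], -tb["log2_fc"], atol=1e-12)
        assert np.allclose(ta["p_value"], tb["p_value"], atol=1e-12)

    def test_identical_clusters_find_nothing(self):
        rng = np.random.default_rng(4)
        norm = _norm_from(rng.poisson(4, size=(120, 20)),
                          [f"g{j}" for j in range(20)])
        labels = pd.Series(
            ["A", "B"] * 60, index=[f"c{i}" for i in range(120)]
        )
        tables = cluster_markers(norm, labels)
        assert (tables["A"].table["fdr"] < 0.05).sum() == 0

    def test_single_cluster_raises(self):
        norm = _norm_from(np.ones((4, 3)), list("abc"))
        labels = pd.Series(["A"] * 4, index=[f"c{i}" for i in range(4)])
        with pytest.raises(ValueError):
            cluster_markers(norm, labels)


class TestSignatureScore:
    def test_constant_matrix_scores_zero(self):
        norm = NormalizedMatrix(
            np.full((5, 30), 2.0), [f"c{i}" for i in range(5)],
            [f"g{j}" for j in range(30)],
        )
        sc = signature_score(norm, [f"g{j}" for j in range(5)], seed=1)
        assert np.allclose(sc.scores, 0.0)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(6)
        norm = _norm_from(rng.poisson(4, size=(30, 40)),
                          [f"g{j}" for j in range(40)])
        s1 = signature_score(norm, ["g1", "g5", "g9"], seed=42)
        s2 = signature_score(norm, ["g1", "g5", "g9"], seed=42)
        assert s1.scores.equals(s2.scores)

    def test_planted_programme_scores_higher_in_perturbed_cells(
        self, recovery_screens
    ):
        run = recovery_screens["planted"]
        up_genes = run["truth"].gene_programmes["A"]
        score = signature_score(run["norm"], up_genes, seed=7)
        a = run["assignment"]
        pert = score.scores.loc[a.singlet_cells("TargetA")]
        ntc = score.scores.loc[a.singlet_cells("NTC")]
        p = ss.mannwhitneyu(pert, ntc, alternative="greater").pvalue
        assert p < 0.01

    def test_shift_of_one_bin_leaves_scores_unchanged(self):
        """Adding a constant to every gene of the signature's bin cancels in
        the control subtraction."""
        rng = np.random.default_rng(8)
        low = rng.uniform(0.0, 0.5, size=(20, 15))
        high = rng.uniform(3.0, 3.5, size=(20, 15))
        values = np.hstack([low, high])
        genes = [f"g{j}" for j in range(30)]
        cells = [f"c{i}" for i in range(20)]
        sig = genes[20:25]  # inside the high bin
        base = signature_score(
            NormalizedMatrix(values, cells, genes), sig, n_bins=2, seed=3
        )
        shifted_vals = values.copy()
        shifted_vals[:, 15:] += 0.2  # whole high bin shifts; binning unchanged
        shifted = signature_score(
            NormalizedMatrix(shifted_vals, cells, genes), sig, n_bins=2, seed=3
        )
        assert np.allclose(base.scores, shifted.scores, atol=1e-12)

    def test_empty_intersection_raises(self):
        norm = _norm_from(np.ones((3, 4)), list("abcd"))
        with pytest.raises(ValueError):
            signature_score(norm, ["nope"])


class TestGateStates:
    def _norm_cell(self, tox, tcf7, havcr2, mki67):
        return [tox, tcf7, havcr2, mki67]

    def test_explicit_gate_assignments(self):
        genes = ["Tox", "Tcf7", "Havcr2", "Mki67"]
        values = np.array(
            [
                [5.0, 5.0, 0.0, 0.0],  # Tox+ Tcf7-hi Havcr2-lo Mki67-lo -> Tpex1
                [5.0, 5.0, 0.0, 4.0],  # -> Tpex2
                [5.0, 0.0, 5.0, 4.0],  # -> Tex1
                [5.0, 0.0, 5.0, 0.0],  # -> Tex2
                [0.0, 5.0, 0.0, 0.0],  # Tox- -> excluded
            ]
        )
        norm = NormalizedMatrix(values, [f"c{i}" for i in range(5)], genes)
        cfg = MarkerConfig(
            tox_threshold=1.0, tcf7_threshold=2.0,
            havcr2_threshold=2.0, mki67_threshold=2.0,
        )
        out = gate_states(norm, cfg)
        assert out.labels.tolist() == ["Tpex1", "Tpex2", "Tex1", "Tex2", "excluded"]

    def test_missing_gate_gene_raises(self):
        norm = _norm_from(np.ones((3, 2)), ["Tox", "Tcf7"])
        with pytest.raises(ValueError, match="Havcr2"):
            gate_states(norm)

    def test_planted_states_recovered(self):
        """Marker-driven simulation is gated back to ≥95% accuracy."""
        # bimodal markers: the high mode is far above dropout noise and the
        # low mode is a near-zero mean, so gating tests logic, not dropout
        markers = {"Tox": 6.0, "Tcf7": 2.0, "Havcr2": 2.0, "Mki67": 2.0}
        hi, lo = 16, 0.01
        states = [
            StateSpec("Tpex1", 0.25, {"Tox": 8, "Tcf7": hi, "Havcr2": lo, "Mki67": lo}),
            StateSpec("Tpex2", 0.25, {"Tox": 8, "Tcf7": hi, "Havcr2": lo, "Mki67": hi}),
            StateSpec("Tex1", 0.25, {"Tox": 8, "Tcf7": lo, "Havcr2": hi, "Mki67": hi}),
            StateSpec("Tex2", 0.25, {"Tox": 8, "Tcf7": lo, "Havcr2": hi, "Mki67": lo}),
        ]
        truth = make_modular_truth(
            ["T1"], n_modules=1, genes_per_programme=10, n_programmes=2,
            effect_size=0.0, extra_genes=markers, states=states,
            capture_noise=CaptureNoise(15.0, 0.0, 0.0, 0.0),
            ntc_weight=1.0, seed=5,
        )
        manifest = build_library_manifest(targets=["T1"], seed=31, ntc_constructs=2)
        screen = simulate_screen(truth, manifest, 3000, seed=9)
        norm = log_normalize(screen.expression)
        # thresholds at the midpoint between simulated low/high marker modes
        def midpoint(gene):
            col = norm.values[:, norm.gene_index(gene)]
            return (np.quantile(col, 0.25) + np.quantile(col, 0.75)) / 2

        cfg = MarkerConfig(
            tox_threshold=0.05,  # every planted state is Tox-high
            tcf7_threshold=midpoint("Tcf7"),
            havcr2_threshold=midpoint("Havcr2"),
            mki67_threshold=midpoint("Mki67"),
        )
        out = gate_states(norm, cfg)
        acc = (out.labels.to_numpy() == screen.true_state.to_numpy()).mean()
        assert acc >= 0.95


class TestGenesetFisher:
    def test_worked_overlap_example(self):
        universe = [f"g{i}" for i in range(1000)]
        gene_set = universe[:50]
        de = universe[45:65]  # overlap 5
        out = geneset_fisher(de, {"S": gene_set}, universe)
        assert out.loc["S", "odds_ratio"] == pytest.approx(5 * 935 / (45 * 15))

    def test_overlap_at_expectation_gives_or_near_one(self):
        universe = [f"g{i}" for i in range(1000)]
        gene_set = universe[:100]  # 10% of universe
        de = universe[90:110] + universe[500:580]  # 10/100 in set
        out = geneset_fisher(de, {"S": gene_set}, universe)
        assert out.loc["S", "odds_ratio"] == pytest.approx(1.0, abs=0.15)

    def test_disjoint_set_gives_zero_or(self):
        universe = [f"g{i}" for i in range(100)]
        out = geneset_fisher(universe[:10], {"S": universe[50:60]}, universe)
        assert out.loc["S", "odds_ratio"] == 0.0

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            geneset_fisher(["a"], {"S": ["a"]}, [])


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("SET1\tdesc\tg1\tg2\tg3\nSET2\turl\tg9\n")
    sets = read_gmt(path)
    assert sets == {"SET1": ["g1", "g2", "g3"], "SET2": ["g9"]}
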