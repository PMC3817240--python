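import numpy as np
import pandas as pd
import pytest

from pathsel import SimulationSpec, simulate_neutral_panel, simulate_sweep
from pathsel.selection import (
    EHHCurve,
    ehh,
    gene_window_scan,
    ihh,
    ihs_scan,
    select_candidate_loci,
    window_candidates,
)
from pathsel import GeneAnnotation

from conftest import make_panel
from helpers import ehh_bruteforce


class TestEHH:
    def test_distance_zero_is_one(self):
        panel = make_panel(np.zeros((4, 3)))
        panel.H[:, 1] = [1, 1, 0, 0]
        curve = ehh(panel, 1, "derived")
        assert curve.left[0].tolist() == [0.0, 1.0]
        assert curve.right[0].tolist() == [0.0, 1.0]

    def test_two_identical_pairs_give_one_third(self):
        """4 carriers split into two identical pairs: 2 of the 6 pairs
        remain identical, EHH = 1/3."""
        H = np.array([
            [0, 1, 0],
            [0, 1, 0],
            [1, 1, 1],
            [1, 1, 1],
            [0, 0, 0],
            [0, 0, 0],
        ])
        panel = make_panel(H)
        curve = ehh(panel, 1, "derived")
        assert curve.right[1, 1] == pytest.approx(1 / 3)
        assert curve.left[1, 1] == pytest.approx(1 / 3)

    def test_all_distinct_gives_zero(self):
        H = np.array([
            [0, 1, 0, 0],
            [0, 1, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 0, 0],
        ])
        panel = make_panel(H)
        curve = ehh(panel, 1, "derived")
        assert curve.right[2, 1] == 0.0

    def test_fewer_than_two_carriers_errors(self):
        panel = make_panel(np.zeros((4, 3)))
        panel.H[0, 1] = 1
        with pytest.raises(ValueError, match="fewer than 2"):
            ehh(panel, 1, "derived")

    def test_matches_bruteforce_on_random_toys(self):
        """Partition refinement equals the all-pairs oracle on 50 random
        panels, exactly, at every distance and both allele classes."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n_hap = 2 * int(rng.integers(3, 9))
            m = int(rng.integers(4, 10))
            H = rng.integers(0, 2, size=(n_hap, m))
            core = int(rng.integers(0, m))
            panel = make_panel(H)
            for cls, allele in (("derived", 1), ("ancestral", 0)):
                carriers = np.nonzero(H[:, core] == allele)[0]
                if carriers.size < 2:
                    continue
                curve = ehh(panel, core, cls)
                for step, j in enumerate(range(core + 1, m), start=1):
                    assert curve.right[step, 1] == pytest.approx(
                        ehh_bruteforce(H, carriers, core, j)
                    )
                for step, j in enumerate(range(core - 1, -1, -1), start=1):
                    assert curve.left[step, 1] == pytest.approx(
                        ehh_bruteforce(H, carriers, core, j)
                    )


class TestIHH:
    def make_curve(self, left, right):
        return EHHCurve(0, "derived", 4, np.asarray(left, dtype=float),
                        np.asarray(right, dtype=float), True, True, 0.0)

    def test_rectangle(self):
        """EHH = 1 over 2 cM one side, instant drop to 0 on the other."""
        c = self.make_curve([[0, 1], [1, 1], [2, 1], [2.5, 0]],
                            [[0, 1], [0.5, 0]])
        val, _ = ihh(c)
        # left: 2 cM at EHH 1 plus closing trapezoid (1+0)/2*0.5 = 0.25
        # right: closing trapezoid (1+0)/2*0.5 = 0.25
        assert val == pytest.approx(2.5)

    def test_hand_trapezoid(self):
        c = self.make_curve([[0, 1], [1, 0.5], [2, 0.2], [3, 0.01]],
                            [[0, 1], [1, 0.04]])
        val, truncated = ihh(c)
        left = 0.75 + 0.35 + 0.105  # three trapezoids, last closes below floor
        right = 0.52
        assert val == pytest.approx(left + right)
        assert not truncated

    def test_truncation_after_first_step(self):
        c = self.make_curve([[0, 1], [1, 0.01], [2, 0.0]],
                            [[0, 1], [1, 0.02]])
        val, _ = ihh(c)
        assert val == pytest.approx(0.505 + 0.51)

    def test_edge_without_floor_flags_truncated(self):
        c = self.make_curve([[0, 1], [1, 0.5]], [[0, 1], [1, 0.01]])
        _, truncated = ihh(c)
        assert truncated

    def test_zero_span_errors(self):
        c = self.make_curve([[0, 1]], [[0, 1]])
        with pytest.raises(ValueError, match="zero genetic-map span"):
            ihh(c)


class TestIHSScan:
    def test_label_swap_negates_uihs(self):
        spec = SimulationSpec(n_haplotypes=200, n_snps=120, rng_seed=21)
        panel = simulate_neutral_panel(spec)
        df = ihs_scan(panel)
        j = int(df[df.reason == ""].index[3])
        flipped = simulate_neutral_panel(spec)
        flipped.H[:, j] = 1 - flipped.H[:, j]
        df2 = ihs_scan(flipped)
        assert df2.loc[j, "uihs"] == pytest.approx(-df.loc[j, "uihs"], rel=1e-9)

    def test_row_order_invariance(self):
        spec = SimulationSpec(n_haplotypes=120, n_snps=80, rng_seed=22)
        panel = simulate_neutral_panel(spec)
        df = ihs_scan(panel)
        rng = np.random.default_rng(0)
        panel.H = panel.H[rng.permutation(panel.n_hap)]
        df2 = ihs_scan(panel)
        pd.testing.assert_frame_equal(df, df2)

    def test_maf_filter_strict(self):
        spec = SimulationSpec(n_haplotypes=200, n_snps=120, rng_seed=23)
        panel = simulate_neutral_panel(spec)
        df = ihs_scan(panel, maf_min=0.05)
        daf = panel.derived_freq()
        maf = np.minimum(daf, 1 - daf)
        assert (df.loc[df.reason == "maf", "index"].map(lambda i: maf[i]) <= 0.05).all()
        assert (df.loc[df.reason == "", "index"].map(lambda i: maf[i]) > 0.05).all()

    def test_sweep_signal_monotone_in_final_freq(self):
        """The physical haplotype-length signal |ln(iHH_A/iHH_D)| at the
        core has non-decreasing median as the sweep goes further
        (0.3 -> 0.6 -> 0.8), over 20 seeds.  (The within-panel
        standardized score is deliberately not used here: the sweep's own
        footprint inflates its frequency-bin sd, see docs/methods.md.)"""
        medians = []
        for ff in (0.3, 0.6, 0.8):
            vals = []
            for seed in range(20):
                spec = SimulationSpec(n_haplotypes=400, n_snps=300, rng_seed=300 + seed)
                panel = simulate_neutral_panel(spec)
                daf = panel.derived_freq()
                mid = np.arange(120, 180)
                core = int(mid[np.argmin(np.abs(daf[mid] - 0.12))])
                sw = simulate_sweep(panel, core, ff, seed=seed)
                ia, _ = ihh(ehh(sw, core, "ancestral", floor=0.05))
                idv, _ = ihh(ehh(sw, core, "derived", floor=0.05))
                vals.append(abs(np.log(ia / idv)))
            medians.append(np.median(vals))
        assert medians[0] <= medians[1] <= medians[2]


class TestJoinAndWindows:
    def test_select_candidate_loci_thresholds(self):
        ihs_df = pd.DataFrame({"snp": ["a", "b", "c", "d"], "daf": [0.3] * 4,
                               "ihs": [2.0, -1.7, 1.0, -2.5]})
        assoc = pd.DataFrame({"snp": ["a", "b", "c", "d"],
                              "p": [0.01, 0.04, 0.01, 0.2]})
        out = select_candidate_loci(ihs_df, assoc, 1.65, 0.05)
        assert out["snp"].tolist() == ["a", "b"]  # sorted by |iHS| desc

    def test_empty_join_is_empty_table(self):
        out = select_candidate_loci(
            pd.DataFrame({"snp": [], "daf": [], "ihs": []}),
            pd.DataFrame({"snp": [], "p": []}),
        )
        assert len(out) == 0

    def test_quantile_rule_on_toy_counts(self):
        """Window counts {0,0,1,2,7} with upper fraction 0.10: only the
        count-7 gene is flagged."""
        flags, fractions, _ = window_candidates(
            np.array([0, 0, 1, 2, 7]), np.array([0, 0, 1, 2, 7]), 0.10
        )
        assert flags.tolist() == [False, False, False, False, True]
        assert fractions[-1] == pytest.approx(0.2)

    def test_no_significant_snps_no_candidates(self):
        spec = SimulationSpec(n_haplotypes=200, n_snps=150, rng_seed=24)
        panel = simulate_neutral_panel(spec)
        df = ihs_scan(panel)
        genes = [GeneAnnotation("G", "7", 50_000, 70_000)]
        recs = gene_window_scan(df, genes, panel.variants, sig_threshold=np.inf)
        assert recs[0].n_significant == 0
        assert not recs[0].candidate

    def test_short_window_flagged(self):
        spec = SimulationSpec(n_haplotypes=200, n_snps=40, rng_seed=25)
        panel = simulate_neutral_panel(spec)
        df = ihs_scan(panel)
        genes = [GeneAnnotation("G", "7", 10_000, 20_000)]
        recs = gene_window_scan(df, genes, panel.variants, window_snps=50)
        assert recs[0].short_window
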