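import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lad_shift as ls
from lad_shift.expression_integration import (
    POSITION_CLASSES,
    call_de,
    classify_position,
    concordance,
    cross_system_overlap,
    moderated_t,
    reference_overlap,
)


def make_matrices(n_genes=300, n_de=40, lfc=1.5, sd=0.3, n_rep=3, seed=0):
    r = np.random.default_rng(seed)
    base = r.normal(8, 1.5, n_genes)
    truth = np.zeros(n_genes)
    idx = r.choice(n_genes, n_de, replace=False)
    truth[idx] = r.choice([-lfc, lfc], n_de)
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    ctrl = pd.DataFrame(base[:, None] + r.normal(0, sd, (n_genes, n_rep)), index=genes)
    net = pd.DataFrame((base + truth)[:, None] + r.normal(0, sd, (n_genes, n_rep)), index=genes)
    return net, ctrl, pd.Series(truth, index=genes)


class TestCallDe:
    def test_below_lfc_threshold_is_nc(self):
        # strong statistic but small fold change stays 'nc'
        r = np.random.default_rng(1)
        genes = pd.Index([f"g{i}" for i in range(200)])
        ctrl = pd.DataFrame(r.normal(8, 0.05, (200, 4)), index=genes)
        net = ctrl + 0.4  # highly significant shift below the 0.5 cutoff
        res = call_de(net, ctrl)
        assert (res["de_call"] == "nc").all()
        assert (res["adj_p"] < 0.05).all()

    def test_identical_matrices_no_de(self):
        net, ctrl, _ = make_matrices()
        res = call_de(ctrl.copy(), ctrl)
        assert (res["de_call"] == "nc").all()

    def test_planted_de_sensitivity_and_fdr(self):
        net, ctrl, truth = make_matrices(n_genes=1000, n_de=100, lfc=1.5, sd=0.3, seed=3)
        res = call_de(net, ctrl)
        called = res["de_call"] != "nc"
        sensitivity = called[truth != 0].mean()
        fdr = (truth[called] == 0).mean() if called.any() else 0.0
        assert sensitivity >= 0.9
        assert fdr <= 0.1
        # direction agrees with planted sign
        hits = called & (truth != 0)
        assert (np.sign(res.loc[hits, "log2fc"]) == np.sign(truth[hits])).all()

    def test_too_few_replicates(self):
        genes = pd.Index(["g0"])
        one = pd.DataFrame([[1.0]], index=genes)
        with pytest.raises(ValueError):
            call_de(one, one)


class TestModeratedTAgainstLimma:
    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's lmFit+eBayes on the same matrix."""
        net, ctrl, _ = make_matrices(n_genes=120, n_de=15, seed=7)
        ours = moderated_t(net.to_numpy(), ctrl.to_numpy())
        mat = pd.concat([net, ctrl], axis=1)
        mat.columns = [f"n{i}" for i in range(net.shape[1])] + \
                      [f"c{i}" for i in range(ctrl.shape[1])]
        mat_path = tmp_path / "expr.tsv"
        mat.to_csv(mat_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{mat_path}", row.names=1))
            design <- cbind(Intercept=1, Net=c(rep(1, {net.shape[1]}), rep(0, {ctrl.shape[1]})))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(t=fit$t[, "Net"], p=fit$p.value[, "Net"],
                              lfc=fit$coefficients[, "Net"])
            write.table(out, "{tmp_path}/limma.tsv", sep="\t", quote=FALSE)
        """)
        r_file = tmp_path / "run.R"
        r_file.write_text(script)
        proc = subprocess.run(["Rscript", str(r_file)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        assert np.allclose(ours["log2fc"], limma["lfc"], atol=1e-6)
        assert np.allclose(ours["t"], limma["t"], rtol=1e-4)
        assert np.allclose(ours["p_value"], limma["p"], rtol=1e-3, atol=1e-12)


class TestClassifyPosition:
    lads_ctrl = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [50000]})
    lads_net = pd.DataFrame({"chrom": ["c"], "start": [30000], "end": [90000]})
    drs = pd.DataFrame({"chrom": ["c", "c"], "start": [100000, 200000],
                        "end": [130000, 230000], "dr_class": ["IP", "PI"]})

    def classify(self, start, end):
        genes = pd.DataFrame({"chrom": ["c"], "start": [start], "end": [end]})
        return classify_position(genes, self.lads_ctrl, self.lads_net, self.drs)[0]

    def test_rules(self):
        assert self.classify(35000, 45000) == "PP"   # LAD in both, no DR
        assert self.classify(105000, 110000) == "IP"
        assert self.classify(205000, 215000) == "PI"
        assert self.classify(300000, 310000) == "II"  # in neither LAD
        assert self.classify(10000, 20000) == "AMB"   # control-only LAD, no DR
        assert self.classify(120000, 210000) == "AMB"  # spans IP and PI

    def test_partition_property(self, mini_run):
        truth = mini_run["truth"]
        cfg = mini_run["config"]
        net = cfg.net_conditions[0]
        cls = classify_position(truth.genes, truth.lads_by_condition[cfg.control_label],
                                truth.lads_by_condition[net], truth.drs[net])
        assert cls.isin(POSITION_CLASSES).all()


class TestGeneWindowDelta:
    def test_identical_tracks_zero(self, mini_run):
        cfg = mini_run["config"]
        track = mini_run["tracks"][cfg.control_label]
        delta = ls.gene_window_delta(mini_run["truth"].genes, track, track)
        assert np.nanmax(np.abs(delta.to_numpy())) == 0.0

    def test_constant_shift(self, mini_run):
        cfg = mini_run["config"]
        track = mini_run["tracks"][cfg.control_label]
        shifted = ls.SignalTrack(track.values + 1.0, fragment_map=track.fragment_map)
        delta = ls.gene_window_delta(mini_run["truth"].genes, track, shifted)
        assert np.nanmax(np.abs(delta.to_numpy() - 1.0)) < 1e-9

    def test_planted_delta_at_zero_noise(self):
        cfg = ls.SimulationConfig(
            seed=5, n_chromosomes=1, chrom_length_bp=1_000_000,
            n_constitutive_lads=1, constitutive_lad_len_bp=(150_000, 200_000),
            n_facultative_lads=1, n_drs_per_class=2, dr_len_bp=(100_000, 120_000),
            noise_sd=0.0, reads_per_sample=2_000_000, dispersion=0.0,
            n_genes=50, n_de_genes=10, net_conditions=("NETX",))
        _, fmap = ls.simulate_genome(cfg)
        truth = ls.simulate_truth(cfg)
        tracks = {}
        for cond in cfg.conditions:
            lam, dam = ls.simulate_damid_counts(cfg, truth, cond, fmap)
            tracks[cond] = ls.log2_ratio(ls.CountTrack(lam, fragment_map=fmap),
                                         ls.CountTrack(dam, fragment_map=fmap))
        drs = truth.drs["NETX"]
        ip = drs[drs["dr_class"] == "IP"].iloc[0]
        mid = (ip["start"] + ip["end"]) // 2
        gene = pd.DataFrame({"chrom": [ip["chrom"]], "start": [mid - 500], "end": [mid + 500]})
        # DR is wider than the 100 kb window, so the window sits fully inside:
        # expected delta = lad - nonlad planted difference
        delta = ls.gene_window_delta(gene, tracks["WT"], tracks["NETX"])[0]
        planted = cfg.lad_log2_mean - cfg.nonlad_log2_mean
        assert abs(delta - planted) <= 0.1

    def test_invalid_window(self, mini_run):
        with pytest.raises(ValueError):
            ls.gene_window_delta(mini_run["truth"].genes,
                                 mini_run["tracks"]["WT"], mini_run["tracks"]["WT"], window=0)


def gene_frame(ip_down, ip_up, pi_down, pi_up):
    rows = ([("IP", "down")] * ip_down + [("IP", "up")] * ip_up +
            [("PI", "down")] * pi_down + [("PI", "up")] * pi_up)
    return pd.DataFrame({"position_class": [r[0] for r in rows],
                         "de_call": [r[1] for r in rows],
                         "damid_delta": np.linspace(-1, 1, len(rows))})


class TestConcordance:
    def test_hand_tally(self):
        res = concordance(gene_frame(ip_down=30, ip_up=10, pi_down=10, pi_up=30))
        assert res.n_genes == 80
        assert res.expected_direction_fraction == pytest.approx(0.75)
        assert res.fisher_p == pytest.approx(
            stats.fisher_exact([[10, 30], [30, 10]])[1])

    def test_all_concordant_boundary(self):
        res = concordance(gene_frame(ip_down=20, ip_up=0, pi_down=0, pi_up=20))
        assert res.expected_direction_fraction == 1.0

    def test_empty_table(self):
        genes = pd.DataFrame({"position_class": ["II"], "de_call": ["nc"],
                              "damid_delta": [0.0]})
        with pytest.warns(UserWarning):
            res = concordance(genes)
        assert np.isnan(res.expected_direction_fraction)

    def test_swap_symmetry(self):
        # exchanging IP<->PI together with up<->down leaves the fraction fixed
        a = concordance(gene_frame(ip_down=25, ip_up=7, pi_down=13, pi_up=19))
        b = concordance(gene_frame(ip_down=19, ip_up=13, pi_down=7, pi_up=25))
        assert a.expected_direction_fraction == pytest.approx(b.expected_direction_fraction)

    def test_simulated_rate_recovery(self):
        cfg = ls.SimulationConfig(seed=11, n_genes=5000, n_de_genes=1000,
                                  de_repositioned_fraction=0.5, net_conditions=("NET29",))
        truth = ls.simulate_truth(cfg)
        expr = ls.simulate_expression(cfg, truth)
        de = call_de(expr["NET29"], expr["WT"])
        genes = truth.genes.join(de[["de_call"]])
        genes["position_class"] = classify_position(
            genes, truth.lads_by_condition["WT"], truth.lads_by_condition["NET29"],
            truth.drs["NET29"])
        res = concordance(genes)
        assert 0.66 <= res.expected_direction_fraction <= 0.74


class TestReferenceOverlap:
    def make_genes(self, calls):
        return pd.DataFrame({"de_call": calls},
                            index=pd.Index([f"g{i}" for i in range(len(calls))]))

    def test_disjoint_supports_full_d(self):
        genes = self.make_genes(["up", "up", "up", "nc", "nc", "nc"])
        ref = pd.Series([4.0, 5.0, 6.0, 1.0, 2.0, 3.0], index=genes.index)
        res = reference_overlap(genes, ref)
        # NET-up genes {4,5,6} vs background {1..6}: D = 0.5 by ecdf enumeration
        assert res.ks_up[0] == pytest.approx(0.5)

    def test_threshold_counts(self):
        genes = self.make_genes(["up", "down", "up", "nc"])
        ref = pd.Series([2.0, 1.5, 0.1, 3.0], index=genes.index)
        res = reference_overlap(genes, ref, threshold_fold=2.0)
        # above log2(2)=1: genes 0 (up), 1 (down), 3 (nc)
        assert res.n_ref_up_threshold == 3
        assert res.net_up_in_ref_up == 1
        assert res.net_down_in_ref_up == 1

    def test_too_few_genes_skips_ks(self):
        genes = self.make_genes(["up", "nc", "nc", "nc"])
        ref = pd.Series([1.0, 2.0, 3.0, 4.0], index=genes.index)
        with pytest.warns(UserWarning, match="KS skipped"):
            res = reference_overlap(genes, ref)
        assert res.ks_up is None

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.integers(3, 50), st.integers(3, 50))
    def test_ks_matches_bruteforce_ecdf(self, seed, n1, n2):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=n1), r.normal(0.3, 1.2, size=n2)
        d_scipy = stats.ks_2samp(x, y).statistic
        pooled = np.concatenate([x, y])
        d_brute = max(abs((x <= v).mean() - (y <= v).mean()) for v in pooled)
        assert d_scipy == pytest.approx(d_brute, abs=1e-12)

    def test_null_p_roughly_uniform(self):
        # NET-up genes drawn from the background: median KS p near 0.5
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            bg = r.normal(size=300)
            sub = r.choice(bg, 40, replace=False)
            ps.append(stats.ks_2samp(sub, bg).pvalue)
        assert 0.3 <= np.median(ps) <= 0.7


class TestCrossSystemOverlap:
    def test_set_arithmetic(self):
        res = cross_system_overlap({"g1", "g2", "g3"}, {"g2", "g3", "g4"},
                                   {f"g{i}" for i in range(1, 11)})
        assert res.n_intersection == 2
        assert res.fraction_a_in_b == pytest.approx(2 / 3)
        assert res.n_a_only == 1 and res.n_b_only == 1

    def test_identical_sets_minimal_p(self):
        uni = {f"g{i}" for i in range(30)}
        a = {f"g{i}" for i in range(8)}
        res = cross_system_overlap(a, a, uni)
        assert res.fraction_a_in_b == 1.0
        assert res.hypergeom_p == pytest.approx(stats.hypergeom.sf(7, 30, 8, 8))

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            cross_system_overlap({"a"}, {"a"}, set())

    def test_null_p_uniform_over_seeds(self):
        uni = list(range(500))
        ps = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = set(r.choice(uni, 50, replace=False).tolist())
            b = set(r.choice(uni, 50, replace=False).tolist())
            ps.append(cross_system_overlap(a, b, set(uni)).hypergeom_p)
        assert 0.25 <= np.median(ps) <= 0.75
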