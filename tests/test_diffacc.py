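import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from chromdar.diffacc import (BlockCorrelation, VoomData, bh_adjust,
                              cell_means_design, consensus_correlation,
                              contrast_vector, differential_accessibility,
                              ebayes_moderate, fit_contrasts, fit_variance_prior,
                              label_dars, tmm_factors, voom_transform, ContrastFit)
from chromdar.errors import ValidationError
from chromdar.intervals import RegionSet
from chromdar.quant_qc import CountExperiment


def make_experiment(counts, meta):
    counts = np.asarray(counts)
    regions = RegionSet.from_tuples(
        [("chr1", i * 1000, i * 1000 + 100) for i in range(counts.shape[0])])
    return CountExperiment(regions=regions, counts=counts, samples=meta)


def simple_meta(n, treatments=None, individuals=None, times=None):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "individual": individuals or ["A"] * n,
        "treatment": treatments or ["VEH"] * n,
        "time": times or ["3"] * n,
    })


class TestTmm:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 500, size=200)
        exp = make_experiment(np.column_stack([col, col, col]), simple_meta(3))
        nf = tmm_factors(exp)
        assert np.allclose(nf.factors, 1.0)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_pure_scaling_equalizes_cpm(self, rng):
        col = rng.integers(10, 500, size=500)
        exp = make_experiment(np.column_stack([col, 2 * col]), simple_meta(2))
        nf = tmm_factors(exp)
        cpm = exp.counts / nf.effective_lib_sizes
        assert np.allclose(cpm[:, 0], cpm[:, 1], rtol=1e-9)

    def test_permutation_equivariance(self, rng):
        counts = rng.negative_binomial(5, 0.1, size=(300, 4))
        exp = make_experiment(counts, simple_meta(4))
        nf = tmm_factors(exp)
        perm = [2, 0, 3, 1]
        exp_p = make_experiment(counts[:, perm], simple_meta(4))
        nf_p = tmm_factors(exp_p)
        assert np.allclose(nf_p.factors, nf.factors[perm])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger_reference(self, rng, tmp_path):
        counts = rng.negative_binomial(5, 0.05, size=(400, 6))
        counts[:, 3] = (counts[:, 3] * 2.5).astype(int)  # composition shift
        exp = make_experiment(counts, simple_meta(6))
        nf = tmm_factors(exp)
        np.savetxt(tmp_path / "counts.tsv", counts, delimiter="\t", fmt="%d")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'counts <- as.matrix(read.table("{tmp_path}/counts.tsv"))\n'
            'dge <- calcNormFactors(DGEList(counts=counts), method="TMM")\n'
            'cat(paste(dge$samples$norm.factors, collapse=","))\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(x) for x in out.stdout.strip().split(",")])
        assert np.allclose(nf.factors, ref, atol=1e-8)


class TestVoom:
    def design(self, meta):
        return cell_means_design(meta)[0]

    def test_homoscedastic_data_gets_flat_weights(self, rng):
        # NB with very low dispersion at high counts: near-constant CV of logs
        meta = simple_meta(8, treatments=["D"] * 4 + ["VEH"] * 4)
        mu = np.full((2000, 8), 1000.0) * rng.uniform(0.5, 2.0, size=(2000, 1))
        counts = rng.poisson(mu)
        exp = make_experiment(counts, meta)
        nf = tmm_factors(exp)
        v = voom_transform(exp, nf, self.design(meta))
        assert v.w.min() > 0 and np.isfinite(v.w).all()

    def test_variance_decreasing_in_mean_gives_increasing_weights(self, rng):
        meta = simple_meta(8, treatments=["D"] * 4 + ["VEH"] * 4)
        mu = np.repeat(np.geomspace(5, 5000, 500), 1)[:, None] * np.ones((1, 8))
        n_nb = 10.0
        counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
        exp = make_experiment(counts, meta)
        v = voom_transform(exp, tmm_factors(exp), self.design(meta))
        low = v.w[:100].mean()
        high = v.w[-100:].mean()
        assert high > low  # log2 counts are noisier at low means

    def test_weights_invariant_to_library_scaling(self, rng):
        from chromdar.diffacc import NormFactors
        meta = simple_meta(6, treatments=["D"] * 3 + ["VEH"] * 3)
        counts = rng.negative_binomial(10, 0.02, size=(300, 6))
        exp = make_experiment(counts, meta)
        libs = exp.lib_sizes.astype(float)
        v1 = voom_transform(exp, NormFactors(np.ones(6), libs), self.design(meta))
        v2 = voom_transform(exp, NormFactors(np.ones(6), libs * 100), self.design(meta))
        assert np.allclose(v1.w, v2.w, rtol=1e-3)


class TestConsensusCorrelation:
    def gaussian_voom(self, rng, icc, R=800, n_ind=4, reps=6):
        inds = [chr(65 + i) for i in range(n_ind)]
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n_ind * reps)],
            "individual": np.repeat(inds, reps),
            "treatment": ["T"] * (n_ind * reps),
            "time": list(np.tile([str(t) for t in range(reps)], n_ind)),
        })
        X, _ = cell_means_design(meta)
        b = rng.normal(0, np.sqrt(icc), size=(R, n_ind))
        ind_idx = np.repeat(np.arange(n_ind), reps)
        y = b[:, ind_idx] + rng.normal(0, np.sqrt(1 - icc), size=(R, len(meta)))
        voom = VoomData(y=y, w=np.ones_like(y), design=X, trend_x=np.zeros(1),
                        trend_y=np.ones(1), meta=meta)
        return voom, meta, X

    @pytest.mark.parametrize("icc,tol", [(0.0, 0.08), (0.5, 0.12)])
    def test_recovers_planted_intraclass_correlation(self, rng, icc, tol):
        voom, meta, X = self.gaussian_voom(rng, icc)
        bc = consensus_correlation(voom, meta["individual"], X)
        assert bc.rho_consensus == pytest.approx(icc, abs=tol)

    def test_single_block_errors(self, rng):
        voom, meta, X = self.gaussian_voom(rng, 0.2, R=20)
        meta = meta.assign(individual="A")
        with pytest.raises(ValidationError):
            consensus_correlation(voom, meta["individual"], X)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_duplicate_correlation(self, rng, tmp_path):
        voom, meta, X = self.gaussian_voom(rng, 0.4, R=400)
        bc = consensus_correlation(voom, meta["individual"], X)
        np.savetxt(tmp_path / "y.tsv", voom.y, delimiter="\t")
        meta.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        script = tmp_path / "dc.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'y <- as.matrix(read.table("{tmp_path}/y.tsv"))\n'
            f'meta <- read.table("{tmp_path}/meta.tsv", header=TRUE, sep="\\t", colClasses="character")\n'
            'design <- model.matrix(~0+factor(meta$time))\n'
            'dc <- duplicateCorrelation(y, design, block=meta$individual)\n'
            'cat(dc$consensus)\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        assert bc.rho_consensus == pytest.approx(float(out.stdout.strip()), abs=0.05)


class TestFitContrasts:
    def test_rho_zero_matches_normal_equations_on_hand_example(self):
        # 6 observations, unit weights, 2 cells, known closed form: cell means
        meta = simple_meta(6, treatments=["D", "D", "D", "VEH", "VEH", "VEH"],
                           individuals=list("ABCABC"))
        X, cells = cell_means_design(meta)
        y = np.array([[1.0, 2.0, 3.0, 0.5, 1.0, 1.5]])
        voom = VoomData(y=y, w=np.ones_like(y), design=X, trend_x=np.zeros(1),
                        trend_y=np.ones(1), meta=meta)
        fit = fit_contrasts(voom, 0.0, X, contrasts=[("D", "3")], cells=cells,
                            vehicle="VEH", block=meta["individual"])
        beta_hand = np.linalg.solve(X.T @ X, X.T @ y[0])
        c = contrast_vector(cells, "D", "3", "VEH")
        assert fit.coef[0, 0] == pytest.approx(c @ beta_hand, abs=1e-10)
        assert fit.coef[0, 0] == pytest.approx(2.0 - 1.0)

    def test_identical_groups_give_zero_log2fc(self):
        meta = simple_meta(4, treatments=["D", "D", "VEH", "VEH"],
                           individuals=list("ABAB"))
        X, cells = cell_means_design(meta)
        y = np.array([[2.0, 3.0, 2.0, 3.0]])
        voom = VoomData(y=y, w=np.ones_like(y), design=X, trend_x=np.zeros(1),
                        trend_y=np.ones(1), meta=meta)
        fit = fit_contrasts(voom, 0.3, X, contrasts=[("D", "3")], cells=cells,
                            vehicle="VEH", block=meta["individual"])
        assert fit.coef[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_rho_zero_reduces_to_weighted_least_squares(self, rng):
        meta = simple_meta(8, treatments=["D"] * 4 + ["VEH"] * 4,
                           individuals=list("ABCDABCD"))
        X, cells = cell_means_design(meta)
        y = rng.normal(size=(5, 8))
        w = rng.uniform(0.5, 2.0, size=(5, 8))
        voom = VoomData(y=y, w=w, design=X, trend_x=np.zeros(1),
                        trend_y=np.ones(1), meta=meta)
        fit = fit_contrasts(voom, 0.0, X, contrasts=[("D", "3")], cells=cells,
                            vehicle="VEH", block=meta["individual"])
        for r in range(5):
            Xw = X * np.sqrt(w[r])[:, None]
            yw = y[r] * np.sqrt(w[r])
            beta = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
            c = contrast_vector(cells, "D", "3", "VEH")
            assert fit.coef[r, 0] == pytest.approx(c @ beta, abs=1e-10)

    def test_inestimable_contrast_named(self):
        meta = simple_meta(4, treatments=["D", "D", "VEH", "VEH"])
        X, cells = cell_means_design(meta)
        with pytest.raises(ValidationError, match="XYZ"):
            contrast_vector(cells, "XYZ", "3", "VEH")


class TestEbayes:
    def make_fit(self, sigma2, coef=None, df=10):
        R = len(sigma2)
        return ContrastFit(
            coef=np.asarray(coef if coef is not None else np.ones((R, 1))),
            stdev_unscaled=np.ones((R, 1)),
            sigma2=np.asarray(sigma2, float),
            df_resid=df, contrasts=[("D", "3")], region_ids=np.arange(R))

    def test_identical_variances_trigger_full_shrinkage(self):
        fit = self.make_fit([2.0] * 50)
        out = ebayes_moderate(fit)
        assert np.isinf(out.attrs["d0"])
        # t = coef / sqrt(s0^2) for every region
        s0 = out.attrs["s0_squared"]
        assert np.allclose(out["t"], 1.0 / np.sqrt(s0))

    def test_prior_recovery_from_simulated_variances(self, rng):
        d0_true, s0_true, df = 8.0, 1.5, 12
        R = 20000
        # s^2 | sigma^2 ~ sigma^2 chi2_df / df with sigma^2 ~ s0*d0/chi2_d0
        sig2 = s0_true * d0_true / rng.chisquare(d0_true, size=R)
        s2 = sig2 * rng.chisquare(df, size=R) / df
        d0, s0 = fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_null_type_one_error_calibration(self, rng):
        # Gaussian null with heterogeneous variances: p < 0.05 at ~5%
        R, n = 5000, 8
        meta = simple_meta(n, treatments=["D"] * 4 + ["VEH"] * 4,
                           individuals=list("ABCDABCD"))
        X, cells = cell_means_design(meta)
        sig = rng.uniform(0.5, 2.0, size=(R, 1))
        y = rng.normal(0, 1, size=(R, n)) * sig
        voom = VoomData(y=y, w=np.ones_like(y), design=X, trend_x=np.zeros(1),
                        trend_y=np.ones(1), meta=meta)
        fit = fit_contrasts(voom, 0.0, X, contrasts=[("D", "3")], cells=cells,
                            vehicle="VEH", block=meta["individual"])
        out = ebayes_moderate(fit)
        assert (out["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestBhAndLabels:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bounds_and_identity(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    def test_monotone_after_sorting(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_strict_alpha_boundary_and_partition(self):
        table = pd.DataFrame({
            "treatment": ["D"] * 3, "time": ["3"] * 3,
            "log2fc": [1.0, -2.0, 0.5],
            "p": [0.001, 0.03, 0.9],
        })
        out = label_dars(table, alpha=0.05)
        assert set(out["label"]) <= {"DAR", "CAR"}
        assert (out["p_adj"] >= out["p"]).all()
        assert ((out["label"] == "DAR") == (out["p_adj"] < 0.05)).all()
        assert out.loc[out["log2fc"] > 0, "direction"].eq("opening").all()
        none = label_dars(table.assign(p=[0.049, 0.05, 0.9]), alpha=0.0)
        assert (none["label"] == "CAR").all()

    def test_exact_alpha_is_car(self):
        # single test: p_adj == p; 0.05 is not < 0.05
        table = pd.DataFrame({"treatment": ["D", "D"], "time": ["3", "24"],
                              "log2fc": [1.0, 1.0], "p": [0.049, 0.05]})
        out = label_dars(table, alpha=0.05)
        assert out.loc[out["time"] == "3", "label"].iloc[0] == "DAR"
        assert out.loc[out["time"] == "24", "label"].iloc[0] == "CAR"


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestAgainstLimmaPipeline:
    def test_full_engine_matches_limma_voom(self, tmp_path):
        from chromdar.simulate import (SimulationDesign, simulate_annotation,
                                       simulate_counts)
        design = SimulationDesign(n_regions=300, seed=11)
        ann = simulate_annotation(design)
        exp, _, _ = simulate_counts(design, ann)
        res = differential_accessibility(exp)
        np.savetxt(tmp_path / "counts.tsv", exp.counts, delimiter="\t", fmt="%d")
        exp.samples.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        script = tmp_path / "limma.R"
        script.write_text(f'''
suppressMessages({{library(edgeR); library(limma)}})
counts <- as.matrix(read.table("{tmp_path}/counts.tsv"))
meta <- read.table("{tmp_path}/meta.tsv", header=TRUE, sep="\\t", colClasses="character")
group <- factor(paste(meta$treatment, meta$time, sep="."))
design <- model.matrix(~0+group); colnames(design) <- levels(group)
dge <- calcNormFactors(DGEList(counts=counts), method="TMM")
v <- voom(dge, design)
corfit <- duplicateCorrelation(v, design, block=meta$individual)
fit <- lmFit(v, design, block=meta$individual, correlation=corfit$consensus)
cm <- makeContrasts(DOX.24-VEH.24, levels=design)
fit2 <- eBayes(contrasts.fit(fit, cm))
out <- data.frame(fc=fit2$coefficients[,1], p=fit2$p.value[,1])
write.table(out, "{tmp_path}/limma_out.tsv", sep="\\t", quote=FALSE, row.names=FALSE)
cat(corfit$consensus)
''')
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        assert res.correlation.rho_consensus == pytest.approx(
            float(out.stdout.strip()), abs=0.02)
        lim = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
        mine = res.contrast_table("DOX", "24").sort_values("region_index")
        assert np.max(np.abs(lim["fc"].to_numpy() - mine["log2fc"].to_numpy())) < 0.01
        same_call = ((lim["p"].to_numpy() < 0.05) == (mine["p"].to_numpy() < 0.05))
        assert same_call.mean() > 0.98
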