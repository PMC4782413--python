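import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from statsmodels.stats.multitest import multipletests

from omnicount import (
    CountResponse,
    GeneAnnotation,
    InvalidInputError,
    gene_seed,
    genomewide_scan,
    run_test,
    select_window_covariates,
    simulate_response,
    synthetic_genotypes,
)
from omnicount import io as oio
from omnicount.cli import main as cli_main


def make_dataset(tmp_path, n=30, n_genes=4, p=6, seed=0):
    """Small on-disk dataset: counts, dosages, BEDs, strata."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    genes = [f"g{i}" for i in range(n_genes)]
    covs = [f"snp{i}" for i in range(p)]
    X = synthetic_genotypes(n, p, rng=rng)
    counts = np.vstack(
        [simulate_response(X, np.full(p, 0.4), 0.4, rng, baseline=2.0) for _ in genes]
    )
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    cov_df = pd.DataFrame(X.T, index=covs, columns=samples)
    # genes at 1kb intervals on chr1; SNPs scattered nearby
    ann = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [1000 * (i + 1) for i in range(n_genes)],
            "end": [1000 * (i + 1) + 500 for i in range(n_genes)],
            "name": genes,
        }
    )
    pos = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [800, 1200, 2100, 2600, 3300, 4800],
            "end": [801, 1201, 2101, 2601, 3301, 4801],
            "name": covs,
        }
    )
    strata = pd.Series(
        np.repeat(["popA", "popB"], n // 2), index=samples, name="stratum"
    )
    paths = {}
    for key, df, index in [
        ("counts", counts_df, True),
        ("covariates", cov_df, True),
        ("annotations", ann, False),
        ("positions", pos, False),
    ]:
        path = tmp_path / f"{key}.tsv"
        if key in ("annotations", "positions"):
            df.to_csv(path, sep="\t", index=False, header=False)
        else:
            df.to_csv(path, sep="\t", index=index)
        paths[key] = str(path)
    strata_path = tmp_path / "strata.tsv"
    strata.to_csv(strata_path, sep="\t", header=False)
    paths["strata"] = str(strata_path)
    return paths, counts_df, cov_df, ann, pos


class TestIO:
    def test_count_matrix_round_trip(self, tmp_path):
        paths, counts_df, *_ = make_dataset(tmp_path)
        back = oio.read_count_matrix(paths["counts"])
        pd.testing.assert_frame_equal(back, counts_df)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ng1\t3\t-1\n")
        with pytest.raises(InvalidInputError):
            oio.read_count_matrix(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ng1\t3\t1.5\n")
        with pytest.raises(InvalidInputError):
            oio.read_count_matrix(path)

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ng1\t3\ng1\t4\n")
        with pytest.raises(InvalidInputError):
            oio.read_count_matrix(path)

    def test_bed_round_trip_and_validation(self, tmp_path):
        paths, *_ = make_dataset(tmp_path)
        bed = oio.read_bed(paths["positions"])
        assert list(bed.columns) == ["chrom", "start", "end", "name"]
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t100\t50\tx\n")
        with pytest.raises(InvalidInputError):
            oio.read_bed(bad)

    def test_strata_round_trip(self, tmp_path):
        paths, *_ = make_dataset(tmp_path)
        strata = oio.read_strata(paths["strata"])
        assert strata.loc["s0"] == "popA"
        assert strata.size == 30


class TestWindows:
    GENE = GeneAnnotation("g", "chr1", 2000, 2500)

    def _positions(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1", "chr1", "chr2"],
                "start": [999, 1000, 2250, 3499, 2250],
                "name": list("abcde"),
            }
        )

    def test_zero_window_selects_gene_body_only(self):
        idx = select_window_covariates(self.GENE, self._positions(), 0, "gene_body")
        assert list(idx) == [2]

    def test_left_edge_is_closed(self):
        # position exactly at start - w is included
        idx = select_window_covariates(self.GENE, self._positions(), 1000, "gene_body")
        assert list(idx) == [1, 2, 3]

    def test_gene_start_anchor(self):
        idx = select_window_covariates(self.GENE, self._positions(), 1000, "gene_start")
        assert list(idx) == [1, 2]

    def test_hand_enumerated_interval(self):
        # oracle: brute-force interval check position by position
        pos = self._positions()
        w = 1000
        expected = [
            i
            for i, row in pos.iterrows()
            if row["chrom"] == "chr1" and 2000 - w <= row["start"] < 2500 + w
        ]
        got = select_window_covariates(self.GENE, pos, w, "gene_body")
        assert list(got) == expected

    def test_other_chromosome_excluded(self):
        idx = select_window_covariates(self.GENE, self._positions(), 10**6)
        assert 4 not in idx


class TestScan:
    def _scan(self, tmp_path, **kw):
        paths, counts_df, cov_df, ann, pos = make_dataset(tmp_path)
        annotations = [
            GeneAnnotation(r["name"], r["chrom"], r["start"], r["end"])
            for _, r in ann.iterrows()
        ]
        defaults = dict(window_bp=1000, k=100, seed=7, use_offsets=True)
        defaults.update(kw)
        return (
            genomewide_scan(counts_df, cov_df, pos, annotations, **defaults),
            counts_df,
            cov_df,
            pos,
            annotations,
        )

    def test_single_gene_matches_direct_run(self, tmp_path):
        table, counts_df, cov_df, pos, annotations = self._scan(tmp_path)
        gene = annotations[0]
        idx = select_window_covariates(gene, pos, 1000, "gene_body")
        y = counts_df.loc[gene.gene_id].to_numpy()
        m = counts_df.sum(axis=0).to_numpy(dtype=float)
        direct = run_test(
            CountResponse(y, m=m),
            cov_df.iloc[idx].to_numpy().T,
            k=100,
            seed=gene_seed(7, gene.gene_id),
        )
        row = table.set_index("gene").loc[gene.gene_id]
        assert row["p"] == direct.p_value
        assert row["u"] == pytest.approx(direct.u_obs)

    def test_bh_adjustment_is_monotone_above_raw(self, tmp_path):
        table, *_ = self._scan(tmp_path)
        tested = table.dropna(subset=["p"])
        assert (tested["p_bh"] >= tested["p"] - 1e-12).all()

    def test_scan_invariant_to_gene_order(self, tmp_path):
        t1, counts_df, cov_df, pos, annotations = self._scan(tmp_path)
        t2 = genomewide_scan(
            counts_df, cov_df, pos, annotations[::-1], window_bp=1000, k=100, seed=7
        )
        merged = t1.set_index("gene").join(t2.set_index("gene"), rsuffix="_r")
        np.testing.assert_allclose(merged["p"], merged["p_r"])

    def test_scan_deterministic_under_same_seed(self, tmp_path):
        t1, *_ = self._scan(tmp_path)
        t2, *_ = self._scan(tmp_path)
        pd.testing.assert_frame_equal(t1, t2)

    def test_constant_gene_skipped_with_flag(self, tmp_path):
        paths, counts_df, cov_df, ann, pos = make_dataset(tmp_path)
        counts_df.loc["g1"] = 5  # constant gene
        annotations = [
            GeneAnnotation(r["name"], r["chrom"], r["start"], r["end"])
            for _, r in ann.iterrows()
        ]
        table = genomewide_scan(counts_df, cov_df, pos, annotations, window_bp=1000, k=50, seed=1)
        assert table.set_index("gene").loc["g1", "flag"] == "constant"
        assert np.isnan(table.set_index("gene").loc["g1", "p"])

    def test_bh_against_direct_sort_oracle(self, rng):
        pvals = rng.uniform(size=37)
        adj = multipletests(pvals, method="fdr_bh")[1]
        # direct step-up oracle
        n = pvals.size
        order = np.argsort(pvals)
        ranked = pvals[order] * n / (np.arange(n) + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.empty(n)
        oracle[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adj, oracle, rtol=1e-12)


class TestCLI:
    def test_run_prints_statistic_and_pvalue(self, tmp_path):
        paths, *_ = make_dataset(tmp_path)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["run", "--counts", paths["counts"], "--covariates", paths["covariates"],
             "--gene", "g0", "-k", "100", "--seed", "3"],
        )
        assert result.exit_code == 0, result.output
        assert "u\t" in result.output and "p\t" in result.output

    def test_scan_writes_result_table(self, tmp_path):
        paths, *_ = make_dataset(tmp_path)
        out = tmp_path / "scan.tsv"
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["scan", "--counts", paths["counts"], "--covariates", paths["covariates"],
             "--positions", paths["positions"], "--annotations", paths["annotations"],
             "-k", "50", "--seed", "1", "-o", str(out)],
        )
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out, sep="\t")
        assert set(["gene", "n_cov", "u", "p", "p_bh", "k", "flag"]) <= set(table.columns)

    def test_missing_annotation_file_is_usage_error(self, tmp_path):
        paths, *_ = make_dataset(tmp_path)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["scan", "--counts", paths["counts"], "--covariates", paths["covariates"],
             "--positions", paths["positions"], "--annotations", "/nonexistent.bed",
             "-o", str(tmp_path / "x.tsv")],
        )
        assert result.exit_code == 2

    def test_joint_command_reports_per_set_and_joint(self, tmp_path):
        paths, *_ = make_dataset(tmp_path)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["joint", "--counts", paths["counts"], "--covariates", paths["covariates"],
             "--covariates", paths["covariates"], "--gene", "g0", "-k", "100"],
        )
        assert result.exit_code == 0, result.output
        assert "joint" in result.output

    def test_simulate_writes_study_table(self, tmp_path):
        out = tmp_path / "study.tsv"
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--factor", "s", "--levels", "1.0", "--n", "30", "--p", "10",
             "--replicates", "5", "-k", "50", "-o", str(out)],
        )
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out, sep="\t")
        assert "auc" in table.columns
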