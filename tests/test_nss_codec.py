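import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oathgwas as og
from oathgwas.nss_codec import (
    EncodeError,
    NSSFormatError,
    QCResult,
    flip_allele,
    qc_filter,
)


class TestEncodeGeneric:
    def test_phenotype_identical_to_covariate(self):
        v = np.array([1.0, 2.0, 5.0, 3.0, 0.0, 4.0, 2.5, 1.5])
        g = og.encode_generic(v, v[:, None])
        var = np.var(v, ddof=1)
        assert np.allclose(g.C, var)

    def test_hand_covariance_denominator_n_minus_1(self):
        # deviations (+-1.5, +-0.5) -> SS = 5, denominator n - 1 = 3
        g = og.encode_generic(np.array([1.0, 2.0, 3.0, 4.0]),
                              np.array([[4.0], [3.0], [2.0], [1.0]]))
        v = 5.0 / 3.0
        assert np.allclose(g.C, [[v, -v], [-v, v]])

    def test_orthogonal_eigenvector_covariates_give_diagonal_block(self):
        sim = og.sim_genotypes(og.SimConfig(n_samples=100, n_loci=300,
                                            n_subpops=2, fst=0.1, seed=5))
        V = og.top_eigenvectors(og.grm(sim.genotypes), 5)
        y = np.random.default_rng(0).normal(size=100)
        g = og.encode_generic(y, V)
        zz = g.C_zz
        off = zz - np.diag(np.diag(zz))
        assert np.abs(off).max() < 1e-10

    def test_zero_variance_covariate_named(self):
        y = np.random.default_rng(1).normal(size=20)
        Z = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(EncodeError, match="C1"):
            og.encode_generic(y, Z, ["C1", "C2"])

    def test_insufficient_sample_size(self):
        with pytest.raises(EncodeError, match="insufficient"):
            og.encode_generic(np.arange(4.0), np.random.default_rng(2).normal(size=(4, 2)))

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        Z = rng.normal(size=(30, 2))
        y2 = y.copy()
        y2[5] = np.nan
        g = og.encode_generic(y2, Z)
        keep = np.ones(30, bool)
        keep[5] = False
        ref = og.encode_generic(y[keep], Z[keep])
        assert g.n == 29
        assert np.allclose(g.C, ref.C)

    def test_phenotype_scaling_equivariance(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=25)
        Z = rng.normal(size=(25, 2))
        c = 3.5
        g1, g2 = og.encode_generic(y, Z), og.encode_generic(c * y, Z)
        assert np.isclose(g2.var_y, c**2 * g1.var_y)
        assert np.allclose(g2.cov_yz, c * g1.cov_yz)
        assert np.allclose(g2.C_zz, g1.C_zz)


class TestEncodeLocus:
    def test_genotype_equal_phenotype(self):
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        locus = og.encode_locus(x, x, snp_id="s")
        assert np.isclose(locus.cov_xy, locus.var_x)

    def test_monomorphic_flagged(self):
        locus = og.encode_locus(np.full(10, 2.0), np.arange(10.0), snp_id="s")
        assert locus.monomorphic and locus.freq_a1 == 1.0 and locus.var_x == 0.0

    def test_hand_values(self):
        locus = og.encode_locus(np.array([0.0, 1.0, 2.0]),
                                np.array([1.0, 2.0, 3.0]), snp_id="s")
        assert np.isclose(locus.var_x, 1.0)
        assert np.isclose(locus.cov_xy, 1.0)
        assert np.isclose(locus.freq_a1, 0.5)

    def test_mean_imputation_and_call_rate(self):
        x = np.array([0.0, 2.0, np.nan, 2.0])
        y = np.array([0.1, 0.4, 0.2, 0.9])
        locus = og.encode_locus(x, y, snp_id="s")
        assert locus.call_rate == 0.75
        xi = np.array([0.0, 2.0, 4.0 / 3.0, 2.0])
        assert np.isclose(locus.cov_xy, np.cov(xi, y, ddof=1)[0, 1])
        assert np.isclose(locus.freq_a1, (4.0 / 3.0) / 2.0)

    def test_all_missing_rejected(self):
        with pytest.raises(EncodeError, match="missing"):
            og.encode_locus(np.full(5, np.nan), np.arange(5.0), snp_id="s")

    def test_out_of_range_rejected(self):
        with pytest.raises(EncodeError, match="outside"):
            og.encode_locus(np.array([0.0, 3.0]), np.arange(2.0), snp_id="s")

    def test_allele_flip_antisymmetry(self, small_dataset):
        y, x, Z = small_dataset
        l1 = og.encode_locus(x, y, Z, snp_id="s", a1="A", a2="G")
        l2 = og.encode_locus(2.0 - x, y, Z, snp_id="s", a1="G", a2="A")
        assert np.isclose(l2.cov_xy, -l1.cov_xy)
        assert np.allclose(l2.cov_xz, -l1.cov_xz)
        assert np.isclose(l2.var_x, l1.var_x)
        assert np.isclose(l2.freq_a1, 1.0 - l1.freq_a1)
        flipped = flip_allele(l1)
        assert np.isclose(flipped.cov_xy, l2.cov_xy)
        assert np.allclose(flipped.cov_xz, l2.cov_xz)

    def test_cauchy_schwarz_holds(self, encoded):
        generic, locus = encoded
        locus.check_cauchy_schwarz(generic)


class TestAssemblePhi:
    def test_no_covariates(self):
        y = np.array([1.0, 2.0, 4.0, 3.0])
        x = np.array([0.0, 1.0, 2.0, 1.0])
        g = og.encode_generic(y)
        locus = og.encode_locus(x, y, snp_id="s")
        phi = og.assemble_phi(g, locus)
        assert phi.M.shape == (2, 2)
        assert np.isclose(phi.M[0, 0], np.var(y, ddof=1))
        assert np.isclose(phi.M[0, 1], locus.cov_xy)
        assert np.isclose(phi.M[1, 1], locus.var_x)

    def test_layout_and_symmetry(self, encoded):
        generic, locus = encoded
        phi = og.assemble_phi(generic, locus)
        assert np.allclose(phi.M, phi.M.T)
        assert np.isclose(phi.M[0, 0], generic.var_y)
        assert np.allclose(phi.M[1, 2:], locus.cov_xz)
        assert np.allclose(phi.M[2:, 2:], generic.C_zz)
        # encoded-from-data Phi is PSD
        assert np.linalg.eigvalsh(phi.M)[0] > -1e-10

    def test_worked_fixture_reassembles(self, worked_phi):
        M = worked_phi.M
        g = og.GenericNSS(n=200, covariate_names=("z1", "z2", "z3"),
                          C=M[np.ix_([0, 2, 3, 4], [0, 2, 3, 4])])
        locus = og.LocusNSS(snp_id="s", chrom="1", pos=1, a1="A", a2="G",
                            freq_a1=0.23, call_rate=1.0, var_x=M[1, 1],
                            cov_xy=M[0, 1], cov_xz=M[1, 2:])
        phi = og.assemble_phi(g, locus)
        assert np.array_equal(phi.M, M)

    def test_dimension_mismatch(self, encoded):
        generic, locus = encoded
        bad = og.LocusNSS(snp_id="s", chrom="1", pos=1, a1="A", a2="G",
                          freq_a1=0.5, call_rate=1.0, var_x=0.5, cov_xy=0.1,
                          cov_xz=np.zeros(2))
        with pytest.raises(ValueError, match="covariate"):
            og.assemble_phi(generic, bad)


def _locus(snp_id="s", freq=0.3, call_rate=1.0, hom=None, biallelic=True):
    return og.LocusNSS(snp_id=snp_id, chrom="1", pos=1, a1="A", a2="G",
                       freq_a1=freq, call_rate=call_rate, var_x=0.4,
                       cov_xy=0.01, cov_xz=np.zeros(0), hom_rate=hom,
                       biallelic=biallelic)


class TestQCFilter:
    @pytest.mark.parametrize(
        "locus, reason",
        [
            (_locus(freq=0.04), "maf"),
            (_locus(biallelic=False), "non-biallelic"),
            (_locus(call_rate=0.99), "callrate"),
            (_locus(hom=0.5), "homozygosity"),
        ],
    )
    def test_removal_reasons(self, locus, reason):
        hom_min = 0.99 if reason == "homozygosity" else None
        result = qc_filter([locus], hom_min=hom_min)
        assert result.kept == []
        assert result.removed[0][1] == reason

    def test_clean_locus_kept(self):
        result = qc_filter([_locus(freq=0.5)])
        assert len(result.kept) == 1 and not result.removed

    def test_strict_maf_boundary(self):
        loci = [_locus(snp_id=f"s{i}", freq=round(0.05 * i, 2)) for i in range(10)]
        result = qc_filter(loci, maf_min=0.05)
        assert len(result.kept) == 9  # freq 0.00 removed; 0.05 kept under "<"
        assert result.counts_by_reason() == {"maf": 1}

    def test_idempotent(self):
        loci = [_locus(snp_id=f"s{i}", freq=f) for i, f in
                enumerate([0.01, 0.2, 0.5, 0.04])]
        once = qc_filter(loci)
        twice = qc_filter(once.kept)
        assert [l.snp_id for l in twice.kept] == [l.snp_id for l in once.kept]
        assert not twice.removed

    def test_empty_input(self):
        assert qc_filter([]) == QCResult(kept=[], removed=[])


class TestExchangeFormat:
    def test_round_trip(self, encoded, tmp_path):
        generic, locus = encoded
        og.write_nss(generic, [locus], tmp_path / "study")
        g2, loci2 = og.read_nss(tmp_path / "study")
        assert g2.n == generic.n
        assert g2.covariate_names == generic.covariate_names
        assert np.allclose(g2.C, generic.C, rtol=1e-9)
        l2 = loci2[0]
        for attr in ("snp_id", "chrom", "pos", "a1", "a2", "biallelic"):
            assert getattr(l2, attr) == getattr(locus, attr)
        for attr in ("freq_a1", "call_rate", "var_x", "cov_xy", "hom_rate"):
            assert np.isclose(getattr(l2, attr), getattr(locus, attr), rtol=1e-9)
        assert np.allclose(l2.cov_xz, locus.cov_xz, rtol=1e-9)

    def test_covariate_count_mismatch_rejected(self, encoded, tmp_path):
        generic, locus = encoded
        og.write_nss(generic, [locus], tmp_path / "a")
        # generic block claiming one extra covariate against the same locus file
        import json
        blob = json.loads((tmp_path / "a.gnss").read_text())
        blob["covariate_names"].append("EXTRA")
        C = np.array(blob["C"])
        C5 = np.eye(5)
        C5[:4, :4] = C
        blob["C"] = C5.tolist()
        (tmp_path / "a.gnss").write_text(json.dumps(blob))
        with pytest.raises(NSSFormatError, match="header mismatch"):
            og.read_nss(tmp_path / "a")

    def test_duplicate_snp_id_rejected(self, encoded, tmp_path):
        generic, locus = encoded
        lines = og.write_nss(generic, [locus], tmp_path / "b")[1].read_text().splitlines()
        (tmp_path / "b.lnss").write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(NSSFormatError, match="duplicate"):
            og.read_nss(tmp_path / "b")

    def test_line_count(self, tmp_path):
        sim = og.sim_genotypes(og.SimConfig(n_samples=50, n_loci=200, seed=9))
        y = np.random.default_rng(9).normal(size=50)
        from oathgwas.synthetic import encode_panel
        generic, loci = encode_panel(sim, y)
        _, lpath = og.write_nss(generic, loci, tmp_path / "c")
        assert len(lpath.read_text().splitlines()) == 201


@given(scale=st.floats(0.1, 10.0))
def test_locus_encoding_scales_with_phenotype(scale, ):
    rng = np.random.default_rng(11)
    x = rng.binomial(2, 0.4, size=40).astype(float)
    y = rng.normal(size=40)
    l1 = og.encode_locus(x, y, snp_id="s")
    l2 = og.encode_locus(x, scale * y, snp_id="s")
    assert np.isclose(l2.cov_xy, scale * l1.cov_xy)
    assert np.isclose(l2.var_x, l1.var_x)
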