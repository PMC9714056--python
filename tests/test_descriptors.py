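import itertools
import math

import numpy as np
import pytest

from amyhex import DescriptorConfig, LabeledDataset, PeptideRecord, extract_all, extract_vector
from amyhex.descriptors import (
    DescriptorError,
    aaindex_encode,
    apaac,
    ctdc,
    ctdd,
    dde,
    egaac,
    gaac,
    gdpc,
    geary,
    moran,
    nmbroto,
    paac,
    qsorder,
    socnumber,
    zscale_encode,
)
from amyhex.tables import AMINO_ACIDS, CODON_COUNTS, CTD_GROUPS, GAAC_GROUPS

CFG = DescriptorConfig()

EXPECTED_DIMS = {
    "aaindex": 3186, "zscale": 30, "egaac": 10, "dde": 400, "gaac": 5,
    "gdpc": 25, "ctdc": 39, "ctdd": 195, "paac": 25, "apaac": 30,
    "qsorder": 50, "socnumber": 10, "nmbroto": 40, "moran": 40, "geary": 40,
}


class TestLayout:
    def test_family_dimension_ledger(self):
        assert CFG.family_dims(6) == {f: EXPECTED_DIMS[f] for f in CFG.family_order}
        assert CFG.dimension(6) == 4125

    def test_full_vector_names_unique_and_finite(self, tables):
        names, vec = extract_vector("NFGAIL", CFG, tables)
        assert len(names) == len(vec) == 4125
        assert len(set(names)) == 4125
        assert np.isfinite(vec).all()

    def test_extract_all_equals_concatenated_families(self, tables):
        ds = LabeledDataset([PeptideRecord("x", "STVIIE", 1)])
        fm = extract_all(ds, CFG, tables)
        names, vec = extract_vector("STVIIE", CFG, tables)
        assert fm.columns == names
        np.testing.assert_array_equal(fm.values[0], vec)

    def test_duplicate_sequences_give_identical_rows(self, tables):
        ds = LabeledDataset(
            [PeptideRecord("a", "KLVFFA", 1), PeptideRecord("b", "KLVFFA", 1)]
        )
        fm = extract_all(ds, CFG, tables)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_mixed_lengths_rejected(self, tables):
        ds = LabeledDataset(
            [PeptideRecord("a", "KLVFFA", 1), PeptideRecord("b", "KLVFF", 0)]
        )
        with pytest.raises(DescriptorError, match="mixed"):
            extract_all(ds, CFG, tables)

    def test_nonstandard_residue_names_record_and_position(self, tables):
        ds = LabeledDataset([PeptideRecord("bad1", "NFGXIL", 1),
                             PeptideRecord("ok", "NFGAIL", 0)])
        with pytest.raises(DescriptorError, match=r"bad1.*'X' at position 4"):
            extract_all(ds, CFG, tables)


class TestCompositionFamilies:
    def test_gaac_homopeptide(self, tables):
        names, v = gaac("AAAAAA", CFG, tables)
        assert dict(zip(names, v))["gaac.aliphatic"] == 1.0
        assert v.sum() == pytest.approx(1.0)

    def test_gaac_hand_count(self, tables):
        # D,E negative; K,R,H positive; C uncharged
        names, v = gaac("DEKRHC", CFG, tables)
        d = dict(zip(names, v))
        assert d["gaac.negative"] == pytest.approx(2 / 6)
        assert d["gaac.positive"] == pytest.approx(3 / 6)
        assert d["gaac.uncharged"] == pytest.approx(1 / 6)
        assert d["gaac.aliphatic"] == d["gaac.aromatic"] == 0.0

    def test_gaac_normalization_and_permutation_invariance(self, tables, random_hexapeptides):
        for seq in random_hexapeptides:
            _, v = gaac(seq, CFG, tables)
            assert v.sum() == pytest.approx(1.0)
            _, v2 = gaac(seq[::-1], CFG, tables)
            np.testing.assert_allclose(v, v2)

    def test_egaac_windows(self, tables):
        names, v = egaac("AAAAAA", CFG, tables)
        assert len(v) == 10  # 2 windows x 5 groups
        d = dict(zip(names, v))
        assert d["egaac.win1.aliphatic"] == d["egaac.win2.aliphatic"] == 1.0
        for w in (1, 2):
            block = [x for n, x in d.items() if f".win{w}." in n]
            assert sum(block) == pytest.approx(1.0)

    def test_egaac_too_short_errors(self, tables):
        with pytest.raises(DescriptorError):
            egaac("AAAA", CFG, tables)

    def test_gdpc_homopeptide_and_oracle(self, tables, random_hexapeptides):
        names, v = gdpc("AAAAAA", CFG, tables)
        assert dict(zip(names, v))["gdpc.aliphatic_aliphatic"] == 1.0
        group_of = {aa: g for g, members in GAAC_GROUPS.items() for aa in members}
        for seq in random_hexapeptides:
            names, v = gdpc(seq, CFG, tables)
            assert v.sum() == pytest.approx(1.0)
            census = {}
            for a, b in zip(seq[:-1], seq[1:]):
                key = f"gdpc.{group_of[a]}_{group_of[b]}"
                census[key] = census.get(key, 0) + 1
            for name, val in zip(names, v):
                assert val == pytest.approx(census.get(name, 0) / 5)

    def test_dde_homopeptide_closed_form(self, tables):
        names, v = dde("AAAAAA", CFG, tables)
        tm = (4 / 61) ** 2
        tv = tm * (1 - tm) / 5
        expected = (1 - tm) / math.sqrt(tv)
        assert dict(zip(names, v))["dde.AA"] == pytest.approx(expected)

    def test_dde_absent_dipeptides_negative(self, tables):
        names, v = dde("AAAAAA", CFG, tables)
        for name, val in zip(names, v):
            if name != "dde.AA":
                assert val < 0

    def test_dde_brute_force_oracle(self, tables, random_hexapeptides):
        for seq in random_hexapeptides:
            names, v = dde(seq, CFG, tables)
            got = dict(zip(names, v))
            for a, b in itertools.product(AMINO_ACIDS, repeat=2):
                dc = sum(
                    1 for i in range(5) if seq[i] == a and seq[i + 1] == b
                ) / 5
                tm = (CODON_COUNTS[a] / 61) * (CODON_COUNTS[b] / 61)
                tv = tm * (1 - tm) / 5
                assert got[f"dde.{a}{b}"] == pytest.approx((dc - tm) / math.sqrt(tv))

    def test_ctdc_homopeptide_group(self, tables):
        names, v = ctdc("AAAAAA", CFG, tables)
        d = dict(zip(names, v))
        # A is in the neutral group of the PRAM900101 hydrophobicity partition
        assert d["ctdc.hydrophobicity_PRAM900101.g2"] == 1.0
        assert d["ctdc.hydrophobicity_PRAM900101.g1"] == 0.0

    def test_ctdc_sums_and_permutation_invariance(self, tables, random_hexapeptides):
        for seq in random_hexapeptides:
            names, v = ctdc(seq, CFG, tables)
            d = dict(zip(names, v))
            for prop in CTD_GROUPS:
                assert sum(d[f"ctdc.{prop}.g{k}"] for k in (1, 2, 3)) == pytest.approx(1.0)
            _, v2 = ctdc(seq[::-1], CFG, tables)
            np.testing.assert_allclose(v, v2)

    def test_ctdd_full_group_quantiles(self, tables):
        names, v = ctdd("AAAAAA", CFG, tables)
        d = dict(zip(names, v))
        prefix = "ctdd.hydrophobicity_PRAM900101.g2"  # the group containing A
        got = [d[f"{prefix}.{pt}"] for pt in ("first", "p25", "p50", "p75", "last")]
        np.testing.assert_allclose(
            got, [100 / 6, 200 / 6, 300 / 6, 500 / 6, 100.0], rtol=1e-9
        )

    def test_ctdd_absent_group_zero_and_range(self, tables, random_hexapeptides):
        names, v = ctdd("AAAAAA", CFG, tables)
        d = dict(zip(names, v))
        assert all(
            d[f"ctdd.hydrophobicity_PRAM900101.g1.{pt}"] == 0.0
            for pt in ("first", "p25", "p50", "p75", "last")
        )
        for seq in random_hexapeptides:
            _, v = ctdd(seq, CFG, tables)
            assert ((v >= 0) & (v <= 100)).all()


class TestPositionalEncodings:
    def test_aaindex_shape_and_lookup(self, tables):
        names, v = aaindex_encode("NFGAIL", CFG, tables)
        assert len(v) == 3186
        d = dict(zip(names, v))
        acc = tables.aaindex.index[0]
        for j, aa in enumerate("NFGAIL"):
            assert d[f"aaindex.{acc}.pos{j + 1}"] == tables.aaindex.loc[acc, aa]

    def test_zscale_homopeptide_repeats_row(self, tables):
        names, v = zscale_encode("KKKKKK", CFG, tables)
        assert len(v) == 30
        expected = np.repeat(tables.zscales["K"].values, 6)
        np.testing.assert_allclose(v, expected)

    @pytest.mark.parametrize("family", [aaindex_encode, zscale_encode])
    def test_positional_block_diff(self, tables, family):
        # sequences differing only at position 3 differ only in pos3 features
        names_a, va = family("NFGAIL", CFG, tables)
        names_b, vb = family("NFWAIL", CFG, tables)
        assert names_a == names_b
        changed = {n for n, a, b in zip(names_a, va, vb) if a != b}
        assert changed, "substitution must change some feature"
        assert all(n.endswith(".pos3") for n in changed)


class TestPseudoComposition:
    def test_paac_homopeptide(self, tables):
        names, v = paac("AAAAAA", CFG, tables)
        d = dict(zip(names, v))
        assert d["paac.A"] == pytest.approx(1.0)
        assert sum(val for n, val in d.items() if n != "paac.A") == pytest.approx(0.0)

    def test_paac_sum_and_brute_force(self, tables, random_hexapeptides):
        props = tables.paac_props.values
        zn = (props - props.mean(axis=1, keepdims=True)) / props.std(axis=1, keepdims=True)
        aa_of = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        for seq in random_hexapeptides:
            names, v = paac(seq, CFG, tables)
            assert v.sum() == pytest.approx(1.0)
            theta = []
            for j in range(1, 6):
                acc = []
                for i in range(6 - j):
                    a, b = aa_of[seq[i]], aa_of[seq[i + j]]
                    acc.append(np.mean([(zn[p, b] - zn[p, a]) ** 2 for p in range(3)]))
                theta.append(np.mean(acc))
            freqs = np.array([seq.count(aa) / 6 for aa in AMINO_ACIDS])
            denom = freqs.sum() + 0.05 * sum(theta)
            expected = np.concatenate([freqs / denom, 0.05 * np.array(theta) / denom])
            np.testing.assert_allclose(v, expected, rtol=1e-10)

    def test_apaac_homopeptide_product_form(self, tables):
        names, v = apaac("AAAAAA", CFG, tables)
        assert len(v) == 30
        props = tables.paac_props.values[:2]
        zn = (props - props.mean(axis=1, keepdims=True)) / props.std(axis=1, keepdims=True)
        iA = AMINO_ACIDS.index("A")
        tau = np.array([zn[p, iA] ** 2 for _ in range(5) for p in range(2)])
        denom = 1.0 + 0.05 * tau.sum()
        d = dict(zip(names, v))
        assert d["apaac.A"] == pytest.approx(1.0 / denom)
        np.testing.assert_allclose(v[20:], 0.05 * tau / denom, rtol=1e-10)

    def test_apaac_sums_to_one(self, tables, random_hexapeptides):
        for seq in random_hexapeptides:
            _, v = apaac(seq, CFG, tables)
            assert v.sum() == pytest.approx(1.0)


class TestSequenceOrder:
    def test_socnumber_homopeptide_zero(self, tables):
        _, v = socnumber("AAAAAA", CFG, tables)
        assert len(v) == 10
        np.testing.assert_allclose(v, 0.0)

    def test_socnumber_nonneg_and_brute_force(self, tables, random_hexapeptides):
        aa_of = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        for seq in random_hexapeptides:
            names, v = socnumber(seq, CFG, tables)
            assert (v >= 0).all()
            got = dict(zip(names, v))
            for which, mat in (
                ("physchem", tables.physchem_distance),
                ("grantham", tables.grantham),
            ):
                for d in range(1, 6):
                    tau = sum(
                        mat.values[aa_of[seq[i]], aa_of[seq[i + d]]] ** 2
                        for i in range(6 - d)
                    )
                    assert got[f"socnumber.{which}.lag{d}"] == pytest.approx(tau)

    def test_qsorder_homopeptide(self, tables):
        names, v = qsorder("AAAAAA", CFG, tables)
        assert len(v) == 50
        d = dict(zip(names, v))
        for which in ("physchem", "grantham"):
            assert d[f"qsorder.{which}.A"] == pytest.approx(1.0)
            block = [val for n, val in d.items() if f".{which}." in n]
            assert sum(block) == pytest.approx(1.0)

    def test_qsorder_blocks_sum_to_one(self, tables, random_hexapeptides):
        for seq in random_hexapeptides:
            names, v = qsorder(seq, CFG, tables)
            d = dict(zip(names, v))
            for which in ("physchem", "grantham"):
                block = [val for n, val in d.items() if f".{which}." in n]
                assert sum(block) == pytest.approx(1.0)


class TestAutocorrelation:
    def test_nmbroto_homopeptide_closed_form(self, tables):
        names, v = nmbroto("AAAAAA", CFG, tables)
        d = dict(zip(names, v))
        iA = AMINO_ACIDS.index("A")
        for p, acc in enumerate(tables.autocorr_props.index):
            expected = tables.autocorr_props.values[p, iA] ** 2
            for lag in range(1, 6):
                assert d[f"nmbroto.{acc}.lag{lag}"] == pytest.approx(expected)

    def test_moran_geary_homopeptide_zero_convention(self, tables):
        for fam in (moran, geary):
            _, v = fam("AAAAAA", CFG, tables)
            np.testing.assert_allclose(v, 0.0)

    def test_all_three_match_brute_force(self, tables, random_hexapeptides):
        aa_of = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        P = tables.autocorr_props.values
        L = 6
        for seq in random_hexapeptides:
            x = np.array([[P[p, aa_of[aa]] for aa in seq] for p in range(8)])
            for fam, kind in ((nmbroto, "nmbroto"), (moran, "moran"), (geary, "geary")):
                names, v = fam(seq, CFG, tables)
                got = dict(zip(names, v))
                for p, acc in enumerate(tables.autocorr_props.index):
                    xp = x[p]
                    xbar = xp.mean()
                    for d in range(1, 6):
                        pairs = [(xp[i], xp[i + d]) for i in range(L - d)]
                        if kind == "nmbroto":
                            exp = np.mean([a * b for a, b in pairs])
                        elif kind == "moran":
                            den = np.mean((xp - xbar) ** 2)
                            exp = (
                                np.mean([(a - xbar) * (b - xbar) for a, b in pairs]) / den
                                if den > 0 else 0.0
                            )
                        else:
                            den = ((xp - xbar) ** 2).sum() / (L - 1)
                            exp = (
                                sum((a - b) ** 2 for a, b in pairs) / (2 * (L - d)) / den
                                if den > 0 else 0.0
                            )
                        assert got[f"{kind}.{acc}.lag{d}"] == pytest.approx(exp), (
                            kind, acc, d, seq,
                        )


class TestOrderSensitivity:
    @pytest.mark.parametrize(
        "family", [aaindex_encode, zscale_encode, egaac, socnumber, nmbroto]
    )
    def test_order_sensitive_families_change_under_swap(self, tables, family):
        # transposition of positions 1 and 4 (N <-> A), not a reversal:
        # pair-sum families are invariant under full reversal
        a = family("NFGAIL", CFG, tables)[1]
        b = family("AFGNIL", CFG, tables)[1]
        assert not np.allclose(a, b)
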