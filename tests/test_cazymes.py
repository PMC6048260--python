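import numpy as np
import pandas as pd
import pytest

from halopond.cazymes import (
    ProteinRecord,
    SubstrateMap,
    cazy_profile,
    family_class,
    salinity_correlation,
    salinity_correlation_by_fraction,
    substrate_for_family,
)
from halopond.stats import bh_adjust
from scipy import stats as sps

ACIDIC_SEQ = "MDEDEDEDDEGSTAEDLLKDE"  # D/E-rich, pI well below 5
BASIC_SEQ = "MKRKKRLAGSTKKRIAKLKRG"  # K/R-rich, pI well above 5


def rec(i, fam, sample="S1", acidic=False):
    return ProteinRecord(
        id=f"p{i}", sequence=ACIDIC_SEQ if acidic else BASIC_SEQ,
        cazy_family=fam, sample_id=sample,
    )


class TestFamilyClass:
    @pytest.mark.parametrize(
        "family, expected",
        [("GH13", "GH"), ("CBM40", "CBM"), ("AA3", "AA"), ("GT81", "GT"),
         ("CE1", "CE"), ("PL9", "PL")],
    )
    def test_class_prefix_parsed(self, family, expected):
        assert family_class(family) == expected

    def test_unparseable_label_warns_and_falls_back(self):
        with pytest.warns(UserWarning, match="xyz9"):
            assert family_class("xyz9") == "other"


class TestSubstrateMap:
    @pytest.mark.parametrize(
        "family, category",
        [("GH5", "cellulose"), ("GH68", "fructans"), ("GH13", "starch"),
         ("GH32", "fructans"), ("GH30", "xylans"), ("GH1", "oligosaccharides"),
         ("GH16", "plant polysaccharides")],
    )
    def test_default_map_entries(self, family, category):
        assert substrate_for_family(family) == category

    def test_unknown_gh_family_is_other(self):
        assert substrate_for_family("GH9999") == "other"

    def test_non_gh_family_is_other(self):
        assert substrate_for_family("GT2") == "other"

    def test_map_is_editable(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("family\tsubstrate\nGH99\tcellulose\n")
        smap = SubstrateMap.from_tsv(path)
        assert smap.category("GH99") == "cellulose"
        assert smap.category("GH13") == "other"


class TestCazyProfile:
    def test_single_acidic_gh_record(self):
        profile = cazy_profile([rec(0, "GH13", acidic=True)])
        assert profile.class_abundance.loc["GH", "S1"] == 1.0
        assert profile.acidic_fraction["S1"] == 1.0

    def test_class_fractions_direct_ratio(self):
        records = [rec(0, "GH13"), rec(1, "GH5"), rec(2, "GT2"), rec(3, "CE1")]
        profile = cazy_profile(records)
        col = profile.class_abundance["S1"]
        assert col["GH"] == 0.5 and col["GT"] == 0.25 and col["CE"] == 0.25
        assert col.sum() == pytest.approx(1.0)

    def test_substrate_fractions_over_gh_only(self):
        records = [rec(0, "GH13"), rec(1, "GH5"), rec(2, "GT2")]
        profile = cazy_profile(records)
        sub = profile.substrate_abundance["S1"]
        assert sub["starch"] == 0.5 and sub["cellulose"] == 0.5
        assert sub.sum() == pytest.approx(1.0)

    def test_acidic_fraction_mixed(self):
        records = [rec(0, "GH13", acidic=True), rec(1, "GH13"), rec(2, "GT2")]
        profile = cazy_profile(records)
        assert profile.acidic_fraction["S1"] == pytest.approx(1 / 3)
        assert profile.acidic_by_class.loc["GH", "S1"] == pytest.approx(0.5)

    def test_per_sample_denominators(self):
        records = [rec(0, "GH13", "S1"), rec(1, "GT2", "S2"), rec(2, "GT2", "S2")]
        profile = cazy_profile(records)
        assert profile.class_abundance.loc["GH", "S1"] == 1.0
        assert profile.class_abundance.loc["GT", "S2"] == 1.0
        assert profile.n_records.tolist() == [1, 2]

    def test_empty_record_set_rejected(self):
        with pytest.raises(ValueError):
            cazy_profile([])


class TestSalinityCorrelation:
    def _features(self):
        sal = pd.Series([2.5, 7.5, 33.2, 5.0, 1.0, 12.0],
                        index=[f"S{i}" for i in range(6)])
        rng = np.random.default_rng(4)
        feats = pd.DataFrame(
            rng.random((10, 6)), columns=sal.index,
            index=[f"f{i}" for i in range(10)],
        )
        feats.loc["f0"] = sal.values  # perfectly tracks salinity
        feats.loc["f1"] = 0.3  # constant
        return feats, sal

    def test_identical_feature_has_r_one_and_is_significant(self):
        feats, sal = self._features()
        res = salinity_correlation(feats, sal)
        assert res.loc["f0", "r"] == pytest.approx(1.0)
        assert res.loc["f0", "significant"]

    def test_constant_feature_excluded(self):
        feats, sal = self._features()
        res = salinity_correlation(feats, sal)
        assert res.loc["f1", "excluded"]
        assert not res.loc["f1", "significant"]
        assert np.isnan(res.loc["f1", "r"])

    def test_p_and_q_match_brute_force(self):
        feats, sal = self._features()
        res = salinity_correlation(feats, sal)
        tested = res[~res["excluded"]]
        ps = []
        for f in tested.index:
            r, p = sps.pearsonr(feats.loc[f], sal)
            assert abs(res.loc[f, "r"] - r) < 1e-12
            assert abs(res.loc[f, "p"] - p) < 1e-9
            ps.append(res.loc[f, "p"])
        assert np.allclose(tested["q"], bh_adjust(ps), atol=1e-12)

    def test_spearman_flag(self):
        feats, sal = self._features()
        res = salinity_correlation(feats, sal, method="spearman")
        rho, p = sps.spearmanr(feats.loc["f2"], sal)
        assert res.loc["f2", "r"] == pytest.approx(rho)
        assert res.loc["f2", "p"] == pytest.approx(p)

    def test_too_few_samples_rejected(self):
        feats, sal = self._features()
        with pytest.raises(ValueError):
            salinity_correlation(feats[["S0", "S1"]], sal)

    def test_split_by_fraction(self):
        feats, sal = self._features()
        meta = pd.DataFrame(
            {
                "pond": list("abcdef"),
                "fraction": ["water"] * 3 + ["sediment"] * 3,
                "salinity_percent": sal.values,
            },
            index=sal.index,
        )
        out = salinity_correlation_by_fraction(feats, meta)
        assert set(out) == {"water", "sediment"}
        assert (out["water"]["n"] == 3).all()
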