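"""Sibship arithmetic, relatedness classification and popgen summaries."""

import numpy as np
import pandas as pd
import pytest

from kinrecruit import (
    GenotypeMatrix,
    PedigreeSpec,
    accept_pairs,
    corroborated_sib_pairs,
    families_from_pairs,
    generate_trc_genotyped,
    kin_summary,
    load_rcs_fixture,
    pairwise_relatedness,
    popgen_stats,
    probability_of_identity,
    rcs_universe,
    sample_panel,
    true_pair_relations,
)
from kinrecruit.kinship import relatedness_to_pairs


# ---- pair acceptance and family arithmetic --------------------------------

def test_fixture_acceptance_counts():
    df = load_rcs_fixture()
    acc = accept_pairs(df, 0.75)
    assert len(acc) == 48
    assert (acc["relation"] == "half_sib").sum() == 45
    assert (acc["relation"] == "full_sib").sum() == 3
    assert (df["relation"] == "half_sib").sum() == 126
    # strict threshold: a posterior of exactly 0.75 is rejected
    assert (df["posterior"] == 0.75).any()
    assert not (acc["posterior"] == 0.75).any()


def test_threshold_zero_keeps_everything():
    df = load_rcs_fixture()
    assert len(accept_pairs(df, 0.0)) == len(df)


def test_fixture_family_structure():
    acc = accept_pairs(load_rcs_fixture(), 0.75)
    part = families_from_pairs(acc, rcs_universe())
    hist = part.size_histogram()
    assert {k: v for k, v in hist.items() if k >= 2} == {2: 20, 3: 10, 4: 1, 5: 1}
    assert sum(1 for f in part.families if len(f) >= 2) == 32


def test_fixture_kin_summary():
    acc = accept_pairs(load_rcs_fixture(), 0.75)
    part = families_from_pairs(acc, rcs_universe())
    summary = kin_summary(part, n=168, n_pairs=48)
    assert summary["recruits_with_kin"] == 79
    assert summary["pct_with_kin"] == pytest.approx(47.0, abs=0.1)
    assert summary["cmax"] == 120
    assert summary["cmax_from_families"] == 121  # redundant within-quadruplet pair


def test_no_pairs_gives_singletons():
    empty = pd.DataFrame(columns=["individual_i", "individual_j", "relation", "posterior"])
    part = families_from_pairs(empty, ["a", "b", "c", "d", "e"])
    assert part.sizes == [1, 1, 1, 1, 1]
    s = kin_summary(part)
    assert s["recruits_with_kin"] == 0 and s["cmax"] == 5


def test_chain_transitivity():
    pairs = pd.DataFrame(
        [("a", "b", "half_sib", 0.9), ("b", "c", "half_sib", 0.9)],
        columns=["individual_i", "individual_j", "relation", "posterior"],
    )
    part = families_from_pairs(pairs, ["a", "b", "c", "d"])
    assert frozenset({"a", "b", "c"}) in part.families
    assert part.sizes == [3, 1]


def test_partition_covers_universe_conservation():
    """recruits_with_kin + singletons == n for arbitrary accepted graphs."""
    rng = np.random.default_rng(5)
    ids = [f"x{i}" for i in range(40)]
    rows = [(ids[a], ids[b], "half_sib", 0.9)
            for a, b in rng.integers(0, 40, size=(30, 2)) if a != b]
    part = families_from_pairs(pd.DataFrame(rows, columns=["individual_i", "individual_j", "relation", "posterior"]), ids)
    s = kin_summary(part)
    assert s["recruits_with_kin"] + s["singletons"] == 40
    assert sorted(sum(([i for i in f] for f in part.families), [])) == sorted(ids)


# ---- genotype container and I/O -------------------------------------------

def small_matrix():
    g = np.array([[0, 1, 2, -1], [1, 1, 0, 2], [2, 0, 1, 1]], dtype=np.int8)
    return GenotypeMatrix(g, ["i1", "i2", "i3"], ["L1", "L2", "L3", "L4"])


def test_allele_frequencies_and_missingness():
    G = small_matrix()
    np.testing.assert_allclose(G.allele_frequencies(), [0.5, 2 / 6, 0.5, 3 / 4])
    np.testing.assert_allclose(G.missing_fraction(), [0.25, 0, 0])


def test_csv_round_trip(tmp_path):
    G = small_matrix()
    path = tmp_path / "geno.csv"
    G.to_csv(path)
    back = GenotypeMatrix.from_csv(path)
    np.testing.assert_array_equal(back.genotypes, G.genotypes)
    assert back.individuals == G.individuals and back.loci == G.loci


def test_genepop_round_trip(tmp_path):
    G = small_matrix()
    path = tmp_path / "geno.gen"
    G.to_genepop(path)
    back = GenotypeMatrix.from_genepop(path)
    np.testing.assert_array_equal(back.genotypes, G.genotypes)
    assert back.individuals == G.individuals


# ---- relatedness classification -------------------------------------------

def test_duplicated_individual_prefers_full_sib(panel300):
    rng = np.random.default_rng(2)
    g = (rng.random((1, 300)) < panel300.frequencies).astype(np.int8) + \
        (rng.random((1, 300)) < panel300.frequencies).astype(np.int8)
    G = GenotypeMatrix(np.vstack([g, g, 2 - g]), ["a", "a_dup", "other"])
    calls = pairwise_relatedness(G, eps=0.01)
    row = calls[(calls.individual_i == "a") & (calls.individual_j == "a_dup")].iloc[0]
    assert row.ll_fs > row.ll_u


def test_unrelated_pairs_called_unrelated(panel300):
    rng = np.random.default_rng(3)
    n = 40
    g = ((rng.random((n, 300, 2)) < panel300.frequencies[None, :, None]).sum(axis=2)).astype(np.int8)
    calls = pairwise_relatedness(GenotypeMatrix(g, [f"u{i}" for i in range(n)]), eps=0.01)
    assert (calls.call == "U").mean() >= 0.97


def test_true_siblings_never_called_unrelated(panel300):
    rng = np.random.default_rng(4)
    spec = PedigreeSpec(n_colonies=10, sires_per_colony=1, dams_per_colony=1,
                        offspring_per_colony=6, missing_rate=0.0)
    G, _, ped = generate_trc_genotyped(60, 6, panel300, spec, rng)
    calls = pairwise_relatedness(G, eps=0.01)
    truth = true_pair_relations(ped)
    m = calls.merge(truth, on=["individual_i", "individual_j"])
    assert (m.relation == "full_sib").all()  # single sire + single dam
    assert (m.call != "U").mean() >= 0.99


def test_two_sire_colonies_mix_fs_and_hs_calls(panel300):
    rng = np.random.default_rng(6)
    spec = PedigreeSpec(n_colonies=12, sires_per_colony=2, dams_per_colony=3,
                        offspring_per_colony=6, missing_rate=0.0)
    G, _, ped = generate_trc_genotyped(72, 6, panel300, spec, rng)
    truth = true_pair_relations(ped)
    calls = pairwise_relatedness(G, eps=0.01)
    m = calls.merge(truth, on=["individual_i", "individual_j"])
    kin = m[m.relation.isin(["full_sib", "half_sib"])]
    assert set(kin.call) >= {"FS", "HS"}


def test_monomorphic_loci_excluded(panel300):
    g = np.array([[0, 1], [0, 2], [0, 1]], dtype=np.int8)  # L1 monomorphic
    calls = pairwise_relatedness(GenotypeMatrix(g, ["a", "b", "c"]), eps=0.05)
    assert len(calls) == 3 and np.isfinite(calls[["ll_u", "ll_hs", "ll_fs"]]).all().all()


def test_pipeline_recovers_families(panel300):
    """Classifier -> corroboration -> partition rebuilds the colony structure."""
    rng = np.random.default_rng(8)
    spec = PedigreeSpec(n_colonies=15, sires_per_colony=1, dams_per_colony=3,
                        offspring_per_colony=6, missing_rate=0.05)
    G, _, ped = generate_trc_genotyped(90, 6, panel300, spec, rng)
    pairs = corroborated_sib_pairs(pairwise_relatedness(G, eps=0.01))
    truth = true_pair_relations(ped)
    key = lambda df: set(map(tuple, df[["individual_i", "individual_j"]].to_numpy()))
    ts, cs = key(truth[truth.relation != "unrelated"]), key(pairs)
    assert len(ts & cs) / len(ts) >= 0.9
    assert len(cs - ts) <= 0.05 * max(len(cs), 1)
    part = families_from_pairs(pairs, G.individuals)
    big = [f for f in part.families if len(f) >= 2]
    assert 13 <= len(big) <= 17


# ---- population-genetic summaries ------------------------------------------

def hwe_sample(freqs, n, rng):
    g = (rng.random((n, freqs.size, 2)) < freqs[None, :, None]).sum(axis=2)
    return GenotypeMatrix(g.astype(np.int8), [f"s{i}" for i in range(n)])


def test_popgen_closed_forms_at_half():
    """Single locus at p = 0.5 in HWE: He = 0.5, Ne = 2, per-locus PI = 0.375."""
    g = np.array([[0], [1], [1], [2]], dtype=np.int8)  # exact HWE counts at p=0.5
    G = GenotypeMatrix(g, list("abcd"))
    stats = popgen_stats(G, G)
    assert stats.he["A"] == pytest.approx(0.5)
    assert stats.ne["A"] == pytest.approx(2.0)
    assert stats.pi["A"] == pytest.approx(0.375)
    assert stats.fst == pytest.approx(0.0, abs=1e-12)


def test_probability_of_identity_product():
    pi = probability_of_identity(np.full(300, 0.5))
    assert np.log(pi) == pytest.approx(300 * np.log(0.375))


def test_popgen_on_simulated_samples(panel300):
    rng = np.random.default_rng(9)
    A = hwe_sample(panel300.frequencies, 60, rng)
    B = hwe_sample(panel300.frequencies, 60, rng)
    stats = popgen_stats(A, B)
    # same source frequencies: high heterozygosity band, negligible divergence
    assert 0.40 < stats.he["A"] < 0.55
    assert stats.fst < 0.01
    assert abs(stats.fis["A"]) < 0.1
    assert stats.n_loci == 300


def test_fis_detects_heterozygote_deficit():
    g = np.array([[0], [0], [2], [2]], dtype=np.int8)  # no heterozygotes at p=0.5
    G = GenotypeMatrix(g, list("abcd"))
    stats = popgen_stats(G, G)
    assert stats.fis["A"] == pytest.approx(1.0)
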