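"""Rule-based calls and Bayesian leave-one-out re-allocation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mytilus_id.assignment import (
    SPECIES_ORDER,
    build_baselines,
    classify_diagnostic,
    classify_me15_16,
    flag_introgression,
    loo_reallocate,
    rm_genotype_probability,
    rm_log_genotype_probability,
)
from mytilus_id.dataset import MarkerGenotype


def moment_oracle(counts, k, genotype):
    """Dirichlet-moment identity for the posterior-predictive genotype
    probability: E[2 p_a p_b] = 2 a_a a_b / (a0 (a0+1)), E[p_a^2] =
    a_a (a_a+1) / (a0 (a0+1)) with a_i = n_i + 1/k, a0 = n + 1."""
    a, b = genotype
    alpha = {al: n + 1.0 / k for al, n in counts.items()}
    for al in (a, b):
        alpha.setdefault(al, 1.0 / k)
    a0 = sum(counts.values()) + 1.0  # k * (1/k) prior mass + n copies
    # note: a0 must equal sum(alpha) over the FULL k-allele registry
    if a == b:
        return alpha[a] * (alpha[a] + 1) / (a0 * (a0 + 1))
    return 2 * alpha[a] * alpha[b] / (a0 * (a0 + 1))


class TestGenotypeProbability:
    def test_monomorphic_baseline_probability_one(self):
        p = rm_genotype_probability({"L": ("a", "a")}, {"L": {"a": 7}}, {"L": 1})
        assert p == pytest.approx(1.0)

    def test_heterozygote_reference_value(self):
        p = rm_genotype_probability({"L": ("a", "b")}, {"L": {"a": 3, "b": 1}}, {"L": 2})
        assert p == pytest.approx(0.35)

    def test_homozygote_reference_value(self):
        p = rm_genotype_probability({"L": ("a", "a")}, {"L": {"a": 3, "b": 1}}, {"L": 2})
        assert p == pytest.approx(0.525)

    def test_zero_k_rejected(self):
        with pytest.raises(Exception):
            rm_genotype_probability({"L": ("a", "a")}, {"L": {}}, {"L": 0})

    def test_loci_multiply_in_log_space(self):
        baseline = {"L1": {"a": 3, "b": 1}, "L2": {"a": 3, "b": 1}}
        k = {"L1": 2, "L2": 2}
        lp = rm_log_genotype_probability({"L1": ("a", "b"), "L2": ("a", "a")}, baseline, k)
        assert lp == pytest.approx(math.log(0.35) + math.log(0.525))

    @given(
        st.lists(st.integers(min_value=0, max_value=12), min_size=2, max_size=5),
        st.booleans(),
    )
    def test_matches_dirichlet_moment_identity(self, counts, homozygote):
        alleles = [f"a{i}" for i in range(len(counts))]
        table = {al: n for al, n in zip(alleles, counts)}
        k = len(alleles)
        genotype = (alleles[0], alleles[0]) if homozygote else (alleles[0], alleles[1])
        p = rm_genotype_probability({"L": genotype}, {"L": table}, {"L": k})
        assert p == pytest.approx(moment_oracle(table, k, genotype), rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_monte_carlo_dirichlet_oracle(self, seed):
        """Average genotype probability over Dirichlet posterior draws."""
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        counts = rng.integers(0, 8, size=k)
        alpha = counts + 1.0 / k
        draws = rng.dirichlet(alpha, size=200_000)
        if seed % 2:  # homozygote a0a0
            sample = draws[:, 0] ** 2
            genotype = ("a0", "a0")
        else:  # heterozygote a0a1
            sample = 2 * draws[:, 0] * draws[:, 1]
            genotype = ("a0", "a1")
        mc, se = sample.mean(), sample.std(ddof=1) / np.sqrt(sample.size)
        table = {f"a{i}": int(c) for i, c in enumerate(counts)}
        p = rm_genotype_probability({"L": genotype}, {"L": table}, {"L": int(k)})
        assert abs(p - mc) < 3 * se + 1e-12


class TestRuleCalls:
    def test_me15_16_homospecific_calls(self, registry):
        me = registry["Me15-16"]
        cases = {
            ("180-E", "180-E"): "edulis",
            ("168-T", "168-T"): "trossulus",
            ("126-G", "126-G"): "galloprovincialis",
            ("126-Ch", "126-Ch"): "chilensis",
        }
        for alleles, species in cases.items():
            assert classify_me15_16(MarkerGenotype("Me15-16", alleles), me).species == species

    def test_me15_16_heterospecific_is_hybrid(self, registry):
        call = classify_me15_16(
            MarkerGenotype("Me15-16", ("168-T", "180-E")), registry["Me15-16"]
        )
        assert call.species == "hybrid(trossulus×edulis)"
        assert call.is_hybrid

    def test_me15_16_missing_unassigned(self, registry):
        call = classify_me15_16(MarkerGenotype("Me15-16", (), missing=True), registry["Me15-16"])
        assert call.is_unassigned

    def test_coi_cut_is_chilensis(self, registry):
        call = classify_diagnostic(MarkerGenotype("COI", ("chilensis-cut",)), registry["COI"])
        assert call.species == "chilensis"

    def test_coi_uncut_is_group(self, registry):
        call = classify_diagnostic(MarkerGenotype("COI", ("uncut",)), registry["COI"])
        assert call.species == "T/E/G" and call.is_group

    def test_its_heterozygote_is_hybrid(self, registry):
        call = classify_diagnostic(MarkerGenotype("ITS", ("EGCh", "tros")), registry["ITS"])
        assert call.is_hybrid and "trossulus" in call.species

    def test_its_common_pattern_is_group(self, registry):
        call = classify_diagnostic(MarkerGenotype("ITS", ("EGCh", "EGCh")), registry["ITS"])
        assert call.species == "E/G/Ch"

    def test_unrecognized_haplotype_unassigned(self, registry):
        registry["COI"].diagnostic_map.pop("uncut")
        call = classify_diagnostic(MarkerGenotype("COI", ("uncut",)), registry["COI"])
        assert call.is_unassigned


def _two_species_rows(n_per_species=5):
    rows = []
    for i in range(n_per_species):
        rows.append((f"e{i}", "ME-1", "mac-1", ("255", "255")))
        rows.append((f"g{i}", "MG-1", "mac-1", ("328", "328")))
    return rows


class TestLooReallocate:
    def test_private_allele_assigns_to_owner_species(self, make_dataset):
        ds = make_dataset(_two_species_rows())
        ref = {f"e{i}": "edulis" for i in range(5)} | {f"g{i}": "galloprovincialis" for i in range(5)}
        results = {r.id: r for r in loo_reallocate(ds, ["mac-1"], reference=ref)}
        assert results["g0"].assigned == "galloprovincialis"
        assert results["e0"].assigned == "edulis"

    def test_identical_baselines_split_scores(self, make_dataset, recwarn):
        # a query individual outside the baselines, scored against two
        # identical species pools, must split its normalized score evenly
        rows = [(f"e{i}", "ME-1", "mac-1", ("255", "255")) for i in range(3)]
        rows += [(f"g{i}", "MG-1", "mac-1", ("255", "255")) for i in range(3)]
        rows += [("q0", "MG-2", "mac-1", ("255", "255"))]
        ds = make_dataset(rows)
        ref = {f"e{i}": "edulis" for i in range(3)} | {f"g{i}": "galloprovincialis" for i in range(3)}
        res = next(r for r in loo_reallocate(ds, ["mac-1"], reference=ref) if r.id == "q0")
        assert res.scores["edulis"] == pytest.approx(0.5)
        assert res.scores["galloprovincialis"] == pytest.approx(0.5)
        # deterministic tie-break follows the fixed species order
        assert res.assigned == "edulis"

    def test_scores_normalize_and_threshold_flags(self, make_dataset):
        ds = make_dataset(_two_species_rows())
        ref = {f"e{i}": "edulis" for i in range(5)} | {f"g{i}": "galloprovincialis" for i in range(5)}
        for r in loo_reallocate(ds, ["mac-1"], reference=ref, threshold=0.05):
            assert sum(r.scores.values()) == pytest.approx(1.0, abs=1e-9)
            assert r.unassigned == (max(r.scores.values()) < 0.05)

    def test_single_individual_baseline_reduces_to_prior(self, make_dataset):
        # with one edulis individual, LOO subtraction empties its baseline:
        # the genotype probability must equal the pure-prior value
        rows = [("e0", "ME-1", "mac-1", ("255", "255"))]
        rows += [(f"g{i}", "MG-1", "mac-1", ("328", "328")) for i in range(3)]
        ds = make_dataset(rows)
        ref = {"e0": "edulis"} | {f"g{i}": "galloprovincialis" for i in range(3)}
        res = next(r for r in loo_reallocate(ds, ["mac-1"], reference=ref) if r.id == "e0")
        k = 2  # alleles 255 and 328 observed across baselines
        prior_only = rm_genotype_probability({"mac-1": ("255", "255")}, {"mac-1": {}}, {"mac-1": k})
        assert math.exp(res.log_probs["edulis"]) == pytest.approx(prior_only)

    def test_adding_back_own_copies_reproduces_non_loo_score(self, make_dataset):
        ds = make_dataset(_two_species_rows())
        ref = {f"e{i}": "edulis" for i in range(5)} | {f"g{i}": "galloprovincialis" for i in range(5)}
        baselines = build_baselines(ds, ["mac-1"], ref)
        res = next(r for r in loo_reallocate(ds, ["mac-1"], reference=ref) if r.id == "e0")
        full = rm_log_genotype_probability(
            {"mac-1": ("255", "255")},
            {"mac-1": baselines.copy_counts("edulis", "mac-1")},
            baselines.k,
        )
        loo_counts = baselines.copy_counts("edulis", "mac-1")
        loo_counts["255"] -= 2
        loo = rm_log_genotype_probability(
            {"mac-1": ("255", "255")}, {"mac-1": loo_counts}, baselines.k
        )
        assert res.log_probs["edulis"] == pytest.approx(loo)
        assert full != pytest.approx(loo)

    def test_unreferenced_individual_scored_without_loo(self, make_dataset):
        rows = _two_species_rows() + [("q1", "MG-2", "mac-1", ("328", "328"))]
        ds = make_dataset(rows)
        ref = {f"e{i}": "edulis" for i in range(5)} | {f"g{i}": "galloprovincialis" for i in range(5)}
        res = {r.id: r for r in loo_reallocate(ds, ["mac-1"], reference=ref)}
        assert res["q1"].assigned == "galloprovincialis"


class TestIntrogressionFlag:
    def test_discordant_species_calls_flagged(self):
        assert flag_introgression("galloprovincialis", "chilensis") == "introgression"

    def test_concordant_not_flagged(self):
        assert flag_introgression("chilensis", "chilensis") is None

    def test_group_call_uninformative(self):
        assert flag_introgression("edulis", "T/E/G") is None
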