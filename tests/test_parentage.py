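"""Trio Mendelian checks and candidate-gene exclusion analysis."""

import numpy as np
import pytest

from equistr.parentage import exclude_candidate_gene, trio_check
from equistr.simulate import PedigreeSpec, gen_trios


def _g(panel, *alleles):
    """Genotype map on the first len(alleles) panel markers."""
    return {m.name: a for m, a in zip(panel.markers, alleles)}


class TestTrioCheck:
    def test_compatible(self, panel):
        r = trio_check(_g(panel, ("12", "15")), _g(panel, ("12", "14")),
                       _g(panel, ("15", "16")), panel)
        assert r.per_locus[0].verdict == "COMPATIBLE"
        assert not r.excluded

    def test_single_step_is_mutation_suspect(self, panel):
        r = trio_check(_g(panel, ("12", "17")), _g(panel, ("12", "14")),
                       _g(panel, ("15", "16")), panel)
        assert r.per_locus[0].verdict == "MUTATION_SUSPECT"

    def test_multi_step_is_mismatch(self, panel):
        r = trio_check(_g(panel, ("12", "19")), _g(panel, ("12", "14")),
                       _g(panel, ("15", "16")), panel)
        assert r.per_locus[0].verdict == "MISMATCH"

    def test_missing_locus_skipped(self, panel):
        r = trio_check(_g(panel, None), _g(panel, ("12", "14")),
                       _g(panel, ("15", "16")), panel)
        assert r.per_locus == []

    def test_exclusion_needs_two_mismatching_loci(self, panel):
        child = _g(panel, ("12", "19"), ("8", "9"))
        dam = _g(panel, ("12", "14"), ("8", "8"))
        sire = _g(panel, ("15", "16"), ("9", "9"))
        assert not trio_check(child, dam, sire, panel).excluded
        child2 = _g(panel, ("12", "19"), ("20", "20"))
        assert trio_check(child2, dam, sire, panel).excluded

    def test_no_false_mismatch_without_mutation(self, panel, study):
        trios = study["trios"]
        by_pop = {}
        for ind in trios.individuals:
            by_pop.setdefault(ind.population, {})[ind.id.split(".")[-1]] = ind
        # the shared study simulates nonzero mutation rates, so allow
        # suspects, but a mutation-free regeneration must be fully compatible
        base = study["base_freqs"]
        ds, truth = gen_trios(base, 50, study["panel"],
                              PedigreeSpec(n_trios=50, rate_scale=0.0), seed=77)
        assert truth == []
        groups = {}
        for ind in ds.individuals:
            groups.setdefault(ind.population, {})[ind.id.split(".")[-1]] = ind
        for trio in groups.values():
            r = trio_check(trio["child"].genotypes, trio["dam"].genotypes,
                           trio["sire"].genotypes, study["panel"])
            assert r.n_mismatch == 0 and r.n_suspect == 0

    def test_mutation_suspect_rate_matches_single_step_share(self, panel):
        # spaced allele grids (4 repeats apart) make every single-step
        # mutation detectable as exactly a one-unit edit
        freqs = {
            m.name: {str(n): 0.25 for n in range(m.ref_repeats,
                                                 m.ref_repeats + 16, 4)}
            for m in panel.markers
        }
        spec = PedigreeSpec(n_trios=1500, single_step_prob=0.9)
        ds, truth = gen_trios(freqs, 1500, panel, spec, seed=11)
        groups = {}
        for ind in ds.individuals:
            groups.setdefault(ind.population, {})[ind.id.split(".")[-1]] = ind
        n_suspect = n_mismatch = 0
        for trio in groups.values():
            r = trio_check(trio["child"].genotypes, trio["dam"].genotypes,
                           trio["sire"].genotypes, panel)
            n_suspect += r.n_suspect
            n_mismatch += r.n_mismatch
        total_rate = sum(m.predicted_mut_rate for m in panel.markers) / 100.0
        exp_events = 2 * 1500 * total_rate          # two meioses per trio
        exp_suspects = 0.9 * exp_events
        se = np.sqrt(exp_suspects)
        assert abs(n_suspect - exp_suspects) <= 3 * se
        # two-step mutations surface as mismatches
        assert n_mismatch <= 0.1 * exp_events + 3 * np.sqrt(0.1 * exp_events) + 1


class TestExclusionRules:
    def test_recessive_excluded_by_separated_heterozygote(self, panel):
        m = panel.get("Eca28")
        aff = {"h1": {m.name: ("10", "12")}}
        r = exclude_candidate_gene("KIT", "28", 3.0, aff, panel.markers,
                                   "RECESSIVE")
        assert r.verdict == "EXCLUDED"
        assert r.evidence[0][0] == "h1"

    def test_recessive_tolerates_one_repeat_heterozygote(self, panel):
        m = panel.get("Eca28")
        aff = {"h1": {m.name: ("10", "11")}}
        r = exclude_candidate_gene("KIT", "28", 3.0, aff, panel.markers,
                                   "RECESSIVE")
        assert r.verdict == "NOT_EXCLUDED"

    def test_dominant_excluded_by_discordant_homozygotes(self, panel):
        m = panel.get("Eca28")
        aff = {"h1": {m.name: ("10", "10")}, "h2": {m.name: ("12", "12")}}
        r = exclude_candidate_gene("NOS1", "28", 3.0, aff, panel.markers,
                                   "DOMINANT_OR_XLINKED")
        assert r.verdict == "EXCLUDED"

    def test_dominant_shared_homozygote_not_excluded(self, panel):
        m = panel.get("Eca28")
        aff = {"h1": {m.name: ("10", "10")}, "h2": {m.name: ("10", "10")}}
        r = exclude_candidate_gene("NOS1", "28", 3.0, aff, panel.markers,
                                   "DOMINANT_OR_XLINKED")
        assert r.verdict == "NOT_EXCLUDED"

    def test_no_flanking_marker_is_untestable(self, panel):
        r = exclude_candidate_gene("FH", "9", 50.0, {}, panel.markers,
                                   "RECESSIVE")
        assert r.verdict == "UNTESTABLE"


class TestExclusionSimulation:
    def test_planted_gene_never_excluded_and_unlinked_rate_matches(self, panel, rng):
        """An IBD-homozygous cohort never excludes the causal gene; unlinked
        markers exclude at the closed-form heterozygote-separation rate."""
        linked = panel.get("Eca28")
        unlinked = panel.get("Eca15")
        alleles = [str(n) for n in range(10, 16)]
        p = rng.dirichlet(np.ones(len(alleles)))
        # closed form: P(het with alleles > 1 repeat apart)
        p_excl = sum(
            2 * p[i] * p[j]
            for i in range(len(alleles)) for j in range(i + 1, len(alleles))
            if abs(int(alleles[i]) - int(alleles[j])) > 1
        )
        n_cohorts, cohort_size = 1000, 13
        excl_hits = 0
        for c in range(n_cohorts):
            crng = np.random.default_rng(9000 + c)
            ibd = str(crng.choice(alleles, p=p))
            aff = {}
            for k in range(cohort_size):
                a, b = crng.choice(alleles, size=2, p=p)
                aff[f"h{k}"] = {linked.name: (ibd, ibd),
                                unlinked.name: tuple(sorted((a, b)))}
            r_lnk = exclude_candidate_gene("CAUSAL", linked.chromosome,
                                           linked.position_mb, aff,
                                           panel.markers, "RECESSIVE")
            assert r_lnk.verdict == "NOT_EXCLUDED"
            r_unl = exclude_candidate_gene("DECOY", unlinked.chromosome,
                                           unlinked.position_mb, aff,
                                           panel.markers, "RECESSIVE")
            excl_hits += r_unl.verdict == "EXCLUDED"
        p_cohort = 1 - (1 - p_excl) ** cohort_size
        se = np.sqrt(p_cohort * (1 - p_cohort) / n_cohorts)
        assert abs(excl_hits / n_cohorts - p_cohort) <= 3 * se + 1e-9
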