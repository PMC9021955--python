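# equistr

A toolkit for building and using tetra/penta-nucleotide STR (microsatellite)
panels for horse DNA profiling and paternity testing.

Horse identification has historically relied on dinucleotide STRs, which
stutter badly (often > 30%) and resist cross-laboratory allele ladders.
Tetra- and penta-nucleotide STRs behave far better but are scarce in the
horse genome.  `equistr` packages the computational side of a 17-plex
tetra/penta-STR panel (plus an amelogenin sex marker): finding and scoring
candidate repeats, screening multiplex primers, turning fragment-analysis
peak tables into named genotypes, and computing the forensic statistics that
make a profile meaningful.  It is aimed at researchers building STR panels
for horses or related species, and at anyone who wants a tested, scriptable
implementation of the underlying statistics.

## The statistics at its core

With allele frequencies `p_i` and power sums `S_k = Σ p_i^k`, each locus
reports

* expected heterozygosity `He = 1 − S2`,
* probability of identity `PI = 2·S2² − S4` (unrelated pair) and
  `PIsib = 1/4 + S2/2 + S2²/2 − S4/4` (full siblings),
* Jamieson–Taylor parentage exclusion powers
  `PE1 = 1 − 4·S2 + 2·S2² + 4·S3 − 3·S4` (first parent) and
  `PE2 = 1 − 2·S2 + S3 + 3(S2·S3 − S5) − 2(S2² − S4)` (second parent, one
  parent known),

and panel-wide values multiply across independently assorting loci.  Repeat
candidacy is judged by a Smith–Waterman-style score against a perfect repeat
array (match +9: a perfect L-bp array scores 9·L) together with the longest
uninterrupted stretch (LUS) of exact motif copies.  A power law
`rate = a·SWS^b` calibrated on the panel reproduces the published per-marker
mutation-rate predictions.

The study's individual genotypes were never released, so the package ships
the published per-marker tables as fixtures and a seed-deterministic
synthetic-data generator (breed-structured frequencies, HWE genotypes, null
alleles, micro-variants, pedigrees with stepwise mutation, electropherogram
peak tables with stutter) for everything that needs genotype-level data.
See `docs/methods.md` for the full model description.

## A worked example

```python
from equistr import load_panel, load_locus_stats, sw_score, fit_power_law
from equistr.panel import Motif, combined_from_locus_table

panel = load_panel()                 # the packaged 17-plex + amel
m = panel.get("Eca20")
print(m.motif.unit, m.sw_score, m.stutter_pct)   # TATC 672 11.2

# score a perfect 9-copy TAAAA array (the panel's Eca04b locus)
print(sw_score("TAAAA" * 9, Motif("TAAAA")))     # 405

# combine the published per-locus table into the panel-wide row
c = combined_from_locus_table(load_locus_stats())
print(f"{c['mean_ho']:.2f} {c['mean_he']:.2f}")          # 0.66 0.72
print(f"{c['combined_pe1']:.2e} {c['combined_pi']:.1e}") # 9.11e-09 1.9e-14

# refit the mutation-rate power law on the panel's (score, rate) pairs
model = fit_power_law([(mk.sw_score, mk.predicted_mut_rate)
                       for mk in panel.markers])
print(f"rate = {model.a:.2e} * SWS^{model.b:.2f}")  # rate = 9.59e-08 * SWS^2.35
```

The combined first-parent value (9.11e-09) is the chance a random horse
survives parentage screening at all 17 markers; the combined PI (≈ 2e-14)
says two unrelated horses essentially never share a full profile.

The `examples/` directory holds one short script per capability (discovery,
panel statistics, genotyping, parentage/exclusion, mutation rates, primer
QC); each prints its numbers with a line on what they mean.  A thin CLI
wraps the common pipelines:

```bash
equistr simulate --seed 7 --out-dir out/
equistr stats out/genotypes.csv --out-dir out/
equistr discover contig.fa --out-dir out/
```

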