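# kinarray

Analysis pipeline for **human-kinase yeast-array growth screens**: ordinal
colony-growth scoring of human kinases expressed in *Saccharomyces
cerevisiae*, condition quality control, kinase activity tiering, cross-strain
concordance, group statistics, phospho-Y2H interaction-modulation calling,
and liquid growth-curve comparison — plus a synthetic-data generator with
planted truth so every stage runs and is testable without any downloads.

## The scientific problem

Ectopic expression of an active human kinase in yeast causes aberrant
phosphorylation of yeast proteins and a measurable growth defect, so colony
growth is a simple in-vivo readout of kinase activity. A screen of this kind
scores hundreds of thousands of yeast spots — kinase × strain × condition ×
replicate — on an ordinal 0–3 scale (none / weak / moderate / severe growth
reduction). Turning those spot scores into kinase activity calls requires a
chain of analysis steps, each implemented here as a tested library module:

| stage | module | what it does |
|---|---|---|
| data model & I/O | `kinarray.screen_model` | long-format score tables, 384-grid parsing, clone→kinase aggregation (`max` over clones/vectors/replicates), referential validation |
| synthetic data | `kinarray.synthetic_screen` | cumulative-logit ordinal score simulator, phospho-Y2H plates, logistic OD curves — all with planted truth |
| condition QC | `kinarray.condition_qc` | per-condition defect counts, bimodal-valley detection, exclusion of globally toxic conditions (defect count > 175), evaluable accounting |
| activity profiling | `kinarray.activity_profiling` | per-strain condition counts, 0–4 bins, Ward clustering into topmost / highly / moderately active tiers, top-30 ranking |
| strain concordance | `kinarray.strain_concordance` | upset decomposition of (kinase, condition) defect pairs by exact strain combination; severe-defect strain histograms |
| group statistics | `kinarray.group_stats` | per-condition-strain group phenotype fractions; self-contained Mann–Whitney rank-sum test (exact enumeration + tie/continuity-corrected normal approximation) |
| phospho-Y2H | `kinarray.phospho_y2h` | dilution-series scoring, baseline estimation, loss/gain modulation calls with an SD3 viability gate, kinase-dead phospho-dependence pairing |
| growth kinetics | `kinarray.growth_kinetics` | four-parameter logistic fits `OD(t) = b + (K−b)/(1+e^{−r(t−t₀)})` to 24 h OD595 series, AUC, WT-vs-kinase-dead effect sizes |

The score model behind the simulator is a cumulative-logit ordinal
regression: for a spot of kinase *k* in strain *s* under condition *c*,

    η = a·activity_k + b·severity_c + γ_s + d_class(k)
    P(score ≥ j) = 1 / (1 + exp(−(η − θ_j)))      j ∈ {1,2,3}

with strictly increasing thresholds θ₁ < θ₂ < θ₃. Controls and kinase-dead
constructs have activity 0. See `docs/methods.md` for the model, parameter
defaults and their rationale.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
reference-scale synthetic screen (266 kinases + 80 controls, 4 strains,
73 conditions, ~368,000 spots) and write their tables under `results/`:

```sh
python analysis/01_simulate_screen.py    # screen tables + planted truth
python analysis/02_condition_qc.py       # toxic-condition exclusion
python analysis/03_activity_profiles.py  # bins, tiers, top-30
python analysis/04_strain_concordance.py # upset counts, severe histogram
python analysis/05_group_comparisons.py  # rank-sum group statistics
python analysis/06_phospho_y2h.py        # modulation calling
python analysis/07_growth_curves.py      # logistic fits, WT vs kinase-dead
```

With the default seed the QC stage prints

```
condition QC:
  defect-count valley estimate: 212.5 (threshold used: 175)
  retained 220 condition-strain pairs (46 excluded as globally toxic)
  per strain: {'BY4742': 61, 'L40c': 58, 'W303': 60, 'Y258': 41}
  conditions retained in every strain: 40
  excluded set equals planted toxic set: True
```

meaning the defect-count distribution is bimodal (valley near 212 kinases
per condition), 46 condition-strain pairs suppress growth globally and are
excluded, and the exclusion recovers exactly the planted toxic conditions.
Profiling then reports

```
activity profiling:
  tier sizes: {'moderately': 135, 'highly': 67, 'topmost': 64}
  active kinases (topmost + highly): 131 (49% of 266)
  tier recovery vs planted truth (ARI): 0.992
```

— the three recovered activity tiers agree with the planted latent tiers at
adjusted Rand index 0.99 — and the group comparison stage finds, as designed
into the generator, that kinases cause phenotypes far more often than
control proteins (rank-sum p ≈ 10⁻⁷⁴ across 220 condition-strain pairs) and
that tyrosine kinases cause severe phenotypes more often than S/T kinases
without a yeast ortholog. The phospho-Y2H stage recovers all planted
interaction modulators with zero false positives and classifies their
kinase-dead partners correctly (catalytic vs scaffold-like), and the growth
stage shows a stress-conditional kinase inhibiting growth only under the
DMSO-style stressor (effect on carrying capacity +0.35 OD under stress vs
−0.00 OD in standard media).

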