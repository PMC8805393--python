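# nntoc — personalised anti-dementia prescription from longitudinal cognitive scores

Four drugs treat the cognitive symptoms of dementia — the
acetylcholinesterase inhibitors **donepezil**, **galantamine** and
**rivastigmine**, and the NMDA-antagonist **memantine** — but they are
prescribed largely by convention rather than by predicted individual
benefit. `nntoc` is a tested implementation of a counterfactual
individualized-treatment-rule pipeline for this setting, aimed at
biostatisticians and ML-for-health researchers who want to study such
recommenders under controlled conditions:

- a **synthetic longitudinal cohort generator** that emulates memory-clinic
  EHR structure (MMSE/MoCA scores on 0–30, irregular visits, heavy
  "not available" demographics, donepezil-dominated prescribing) and
  plants a per-patient ground-truth best drug;
- **preparation**: inclusion/exclusion filters (age 59–102, no
  polypharmacy, two-year follow-up cap, ≥2 observations), one-hot
  missing-as-category encoding, fixed-length left-zero-padded visit
  windows, patient-level 60/40 splits;
- a **score predictor**: fully connected front end + two-layer LSTM
  (pure-numpy autodiff, no deep-learning framework needed), with ridge,
  random-forest and 1-D CNN baselines, minority-drug oversampling and a
  masked-loss multitask (MMSE+MoCA) variant;
- a **recommender**: re-run the fitted model once per candidate drug and
  pick the argmax — the *neural network treatment of choice* (NNToC) —
  with an AChEI-only mode and a shuffled-recommendation null;
- **evaluation statistics**: concordant-vs-discordant decline trajectories,
  Welch's *t* (Welch–Satterthwaite df), Yates-corrected 2×2 chi-square,
  permutation feature importance, and recovery of the planted best drug
  with an exact binomial test.

The core prediction model is

&nbsp;&nbsp;&nbsp;&nbsp;ŷᵢ = f_θ(x_{i,t−w+1}, …, x_{i,t}, d, Δt),

the predicted next-visit score of patient *i* given the last *w* encoded
visits, a candidate drug *d* and the time gap Δt to the target visit; the
recommendation rule is NNToC(i) = argmax_d ŷᵢ(d), and patients are
compared by decline D(t) = s(t_init) − s(t) (positive = worsening).

## Worked example

Run the full pipeline — simulate, filter, split, train, recommend,
evaluate — on an 800-patient synthetic cohort:

```python
from nntoc import PipelineConfig, CohortConfig, ModelSpec, run_pipeline

cfg = PipelineConfig(cohort=CohortConfig(n_patients=800),
                     model=ModelSpec(epochs=300, patience=50),
                     evaluation_visit="random", shuffle_null=True,
                     output_dir="readme_run", global_seed=11)
run_pipeline(cfg)
print(open("readme_run/report.txt").read())
```

which prints:

```
Personalised prescription pipeline report
=========================================
patients (input -> filtered): 800 -> 795
split: 477 train / 318 validation
evaluated patients: 318
concordance rate: 0.2642 (84 concordant / 234 discordant)
recommended drug counts: donepezil=83, galantamine=50, rivastigmine=97, memantine=88
2-year decline (points): concordant -0.56 [0.41] vs discordant 0.75 [0.26]
  gap 1.31; Welch t(70.77) = -2.69, p = 0.008813
planted-best-drug recovery: 0.3553 (95% CI 0.3108-1.0000), p vs chance = 1.88e-05
shuffled-recommendation null: concordance 0.2453, decline gap 0.60
```

Reading the numbers: 5 of 800 simulated patients fall to the inclusion
filters; the model recommends all four drugs, not one blanket choice; the
84 patients who were actually prescribed their recommended drug held
roughly steady over two years (−0.56 points, i.e. slight improvement,
SE 0.41) while the discordant group declined 0.75 points (SE 0.26), a
1.31-point gap with Welch p ≈ 0.009; recommendations match the simulator's
planted best drug for 35.5 % of patients against a 25 % chance level
(exact binomial p ≈ 2 × 10⁻⁵); and handing each patient another patient's
recommendation collapses the gap (0.60) — the recommendations are
personalised, not one drug that "generally works".

The same run is available from the shell:

```bash
nntoc simulate --out cohort.csv --truth truth.csv --seed 3 --n-patients 800
nntoc prep --cohort cohort.csv --out filtered.csv
nntoc run --config config.yaml --seed 11 --out run_dir
```

(`nntoc train`, `nntoc recommend` and `nntoc evaluate` expose the
intermediate stages; see `nntoc --help`.)

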