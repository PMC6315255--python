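# funcprofile

Infer physical function from free-living wearable activity-monitor data.

Clinic-based capacity tests — the 400-m walk time (400MWT), 20-m walk
pace (20MPACE), and the five-repetition sit-to-stand pace (5CSPACE) —
measure what a person *can* do under supervision. A hip-worn
accelerometer records what they actually *do* all day, as activity
counts per minute. `funcprofile` turns week-long minute-epoch count
traces into a compact **function profile** and uses it, together with
clinical covariates, to classify subjects into ordered bands of those
capacity measures. The intended users are biostatisticians and digital
biomarker researchers working with actigraphy cohorts such as
knee-osteoarthritis studies.

## The method

1. **Wear-time filtering.** Continuous runs of zero counts spanning
   more than 90 minutes (allowing interruptions of at most 2
   consecutive minutes, each below 100 counts) are nonwear; days with
   at least 10 h of wear are valid.
2. **Segmentation.** Each wear bout is partitioned into maximal
   homogeneous segments by divisive energy-statistic change-point
   analysis with a seeded permutation test; each segment is indexed by
   its sample mean m and SD s (counts/min).
3. **Pattern classes.** The (m, s) plane up to the reference maxima
   (M, S) is cut into half-open square cells of one interval width w,
   e.g. [2800, 3500) x [0, 700) at w = 700. A segment is an instance
   of the cell it falls in. Chebyshev's inequality on a cell's
   midinterval values (mu, sigma) bounds the counts its instances
   contain: at least 1 - 1/k² of them lie in (mu - k sigma,
   mu + k sigma).
4. **Function profile.** For subject i with K_i valid days,
   a_ij = (1/K_i) Σ_k t_ijk is the average minutes/day spent in class
   j; the profile A_i sums to the subject's mean daily wear time.
5. **Ordinal classification.** Capacity values are cut at the training
   quartiles into categories 1 < 2 < 3. A cumulative-logit additive
   model P(Y ≤ c | X) = logistic(θ_c − Σ_p f_p(X_p)) with penalized
   spline smooths f_p over the descriptor
   D_i = (BMI, age, sex, height, OA subcohort, A_i) is fitted with
   inverse-prevalence observation weights.
6. **Evaluation.** Goodman-Kruskal Gamma — (C − D)/(C + D) over
   concordant and discordant pairs, ties excluded — on held-out
   subjects; the interval width w is tuned by repeated stratified
   5-fold cross-validation.

Because the motivating cohort data are access-restricted, the package
ships a synthetic-cohort generator (`funcprofile.synthetic`) that
emulates their structure: bout-structured minute counts whose
intensity-class mix is tilted by a latent function score, nonwear
blocks, covariates echoing published cohort descriptives, and capacity
measures monotone in the score. Every pipeline stage is tested against
it.

## Worked example

```python
from funcprofile.pipeline import run_pipeline

report = run_pipeline({
    "seed": 17,
    "simulate": {"n_subjects": 60, "n_days": 4},
    "width": 700.0,
    "measures": ["walk400_time"],
})
print(report["measures"]["walk400_time"])
```

prints (numbers from this exact run):

```
{'measure': 'walk400_time', 'interval_width': 700.0,
 'gamma_with_profile': 0.9285714285714286,
 'gamma_without_profile': 0.0,
 'delta': 0.9285714285714286,
 'n_train': 48, 'n_test': 12, 'seed': 1938743972}
```

Sixty synthetic subjects are simulated, wear-filtered, segmented, and
profiled on a width-700 grid; two ordinal models are fitted on a
stratified 80% training split — the full descriptor and a
covariates-only baseline — and evaluated on the 12 held-out subjects.
Held-out Gamma is 0.93 with the function profile against 0.00 without
it: in this cohort the activity profile carries essentially all of the
recoverable signal about 400-m walk category, while the covariates
alone rank the held-out subjects no better than chance.

The same stages are available as a CLI
(`funcprofile simulate|wear|segment|profile|tune|evaluate|run`); see
`funcprofile --help`.

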