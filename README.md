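# snowrsf

Winter space use of alpine ungulates is squeezed between two forces: snow,
which buries food and makes movement costly, and supplemental feeding
sites, which concentrate food at fixed points.  `snowrsf` implements a
complete, reproducible pipeline for quantifying how these two forces
jointly shape a population's winter distribution and how that
distribution shifts between decades and under forecast snow regimes.  It
is aimed at movement ecologists and wildlife managers who have (or want
to prototype against) telemetry relocations, a DEM, snow-depth rasters, a
canopy map and feeding-site coordinates.

## The model

Selection is estimated with a used/available resource selection function
(RSF).  Telemetry fixes, thinned to one per animal per day, are cases
(y = 1); an equal number of random points drawn uniformly within the
population's 99% kernel-density home range are controls (y = 0).  A
logistic regression estimates the selection coefficients of the
exponential RSF

    w(x) = exp[ β₁·CC + β₂·SD + β₃·(1/Dist_FS) + β₄·(SD/Dist_FS) ]

where `CC` is binary canopy cover (1 = forested), `SD` the monthly mean
snow depth (cm), `Dist_FS` the 3-D path distance to the nearest feeding
site (m) — its reciprocal is the "proximity" — and the interaction term
lets feeding-site attraction strengthen with snow depth.  Relative
probability of use is the linearly rescaled selection surface

    Rp = LinScale(w),   LinScale(xᵢ) = (xᵢ − min x) / (max x − min x).

Validation uses ROC AUC and 5-fold cross-validation with Kendall's τ
between prediction-bin rank and area-adjusted frequencies of held-out
use.  Monthly Rp maps are binned into 10 pooled quantiles and compared
pairwise — across years within a period, between decades, and within
forecast scenarios — with Cohen's kappa weighted by rank disagreement;
per-month one-way ANOVA with Tukey HSD tests category differences, and
subtraction maps (later − earlier bin) visualise where use shifted.

A synthetic study system (valley-to-ridge DEM, elevation-lapse snow with
winter-severity structure, canopy patches, two feeding-site densities,
and telemetry sampled from a known ground-truth RSF) makes the whole
pipeline testable end to end without field data.

## Worked example

Run the full default experiment (two periods × three winters × six
winter months, plus two forecast scenarios, on a 110×110 grid at 100 m):

```sh
snowrsf run-all --seed 0 --workdir demo
```

which prints

```
wrote 102 artifacts to demo
historical: beta_cc=+1.346 beta_sd=-0.0406 beta_prox=+450.5 beta_inter=+4.15 AUC=0.982 kfold mean tau=0.827
contemporary: beta_cc=+0.691 beta_sd=-0.0403 beta_prox=+290.3 beta_inter=+3.87 AUC=0.912 kfold mean tau=0.911
```

The fitted slopes recover each period's ground truth (historical truth
1.4 / −0.05 / 450 / 5; contemporary truth 0.8 / −0.05 / 300 / 5): deer
select forest canopy, avoid deep snow, and are attracted to feeding
sites, more strongly so under snow.  AUC near 0.9 and k-fold mean τ
above 0.8 with all fold p < 0.05 indicate a well-calibrated model.
`demo/kappas.csv` holds the weighted-kappa records; averaging them by
month and category gives

```
category  intra_h  intra_c  inter_decadal  intra_i  intra_s
Apr         0.449    0.994          0.001    0.997    0.995
Dec         0.448    0.998          0.001    0.998    0.978
Feb         0.225    0.429          0.002    0.963    0.987
Jan         0.371    0.987          0.001    0.998    0.996
Mar         0.347    0.382          0.003    0.653    0.943
Nov         0.985    0.982          0.001    0.938    0.880
```

— the qualitative fingerprint of the system: year-to-year agreement in
the contemporary period is far higher than in the historical one in
December, January and April (where recent winters have little snow
variability), the two mid-winter months stay variable in both periods,
and inter-decadal agreement is near chance everywhere because both the
feeding-site network and the snow regime changed.  `demo/anova.csv`
carries the per-month ANOVA/Tukey tables with significance stars, and
`demo/subtraction/` the dry-minus-snowy and scenario-minus-contemporary
bin-difference maps (range −9…+9).

Library use mirrors the CLI: `snowrsf.run_experiment(RunConfig(...))`
returns every intermediate object in memory (designs, models, Rp maps,
kappa records, validation reports).

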