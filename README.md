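# mvblife

Model-based multivariate decoding of two-ROI fMRI activity across the
adult lifespan.

Healthy ageing commonly shows *more* prefrontal (PFC) activation alongside
*worse* memory — is the extra activity compensatory (it carries task
information the posterior visual cortex, PVC, no longer provides), or a
symptom of dedifferentiation (more activity, less specificity)?  Mean
activation cannot answer this: the question is about information, not
amplitude.  `mvblife` implements the analysis chain that can — for
cognitive-neuroscience researchers who want the full pipeline on their own
ROI time series, and for methodologists who want a tested, ground-truthed
implementation of multivariate Bayesian (MVB) decoding.

## The model

For each subject, a first-level GLM with canonical-HRF regressors, cosine
high-pass (1/128 Hz) and a pooled AR(1)-plus-white noise model fitted by
ReML yields prewhitened model and data.  MVB then reverses the mapping: a
psychological target variable `t = Xc` (subsequent memory, or a linear
working-memory load contrast) is predicted from voxel activity under the
hierarchical empirical-Bayes model

```
R t = R Y U η + ε,    η ~ N(0, Σ_η),    ε ~ N(0, σ² I)
```

with `R` a projector removing all design columns outside the contrast,
`U` a sparse (one pattern per voxel) or smooth (Gaussian FWHM 8 mm)
spatial pattern basis, and Σ_η variance components over nested pattern
subsets optimised by a greedy search that maximises the free energy `F`
(the log-evidence bound).  Models are compared by ΔF with ±3 nats as the
strong-evidence threshold:

- **decodability** — F(real target) − mean F over 20 phase-shuffled
  surrogate targets, the inclusion gate;
- **weight spread** — SD of posterior voxel weights, indexing how many
  voxels carry information;
- **boost** — whether a joint PVC+PFC model beats a PVC-only model by >3
  nats, the direct test of a compensatory prefrontal contribution;
- **top-voxel PFC proportion** — the anterior share of voxels with
  |w − mean| > 2 SD in the joint model.

Group-level age effects use robust quadratic regression (Huber
M-estimation on standardized age and age²), proportional-odds ordinal
regression for boost outcomes, and directional Bayes factors with a
half-normal(0, 1) effect prior.

Real lifespan cohort data are access-controlled, so the package includes a
first-class synthetic cohort generator: the analysis GLM run generatively
with AR(1) voxel noise plus an ROI-shared physiological component, under
named ground-truth scenarios (`dedifferentiation`, `compensation`,
`null`, ...) whose univariate amplitude and multivariate information vary
with age in known ways.

## Worked example

Simulate a 24-subject dedifferentiation cohort (ages 20–88, 120
voxels/ROI), run the full pipeline, and look at the group table:

```python
import mvblife as mv
from mvblife.cohort import CohortSpec
from mvblife.config import RunConfig

cfg = RunConfig(
    cohort=CohortSpec(n_subjects=24, scenario="dedifferentiation",
                      n_voxels_per_roi=120),
    shuffle_reps=5, exclusion_policy="both", seed=7)
res = mv.run_pipeline(cfg, out_dir="results/demo")
print(res.group_table[["measure", "roi", "n", "linear_t", "linear_p"]])
```

```
           measure   roi  n  linear_t  linear_p
   univariate_mean   PVC 24   -0.2923    0.7701
   univariate_mean   PFC 24    3.7815    0.0002
     weight_spread   PVC 24   -7.9933    0.0000
     weight_spread   PFC 24   -6.5388    0.0000
top_pfc_proportion joint 24    1.5790    0.1143
      decodability   PVC 24    8.0733    0.0000
     boost_ordinal joint 24   -2.2085    0.0272
```

Reading the rows: PFC mean activation **rises** with age (linear t = 3.78,
p = 0.0002) while PVC does not — the classic posterior-to-anterior pattern
— yet the spread of decoding weights **falls** in both ROIs (t ≈ −7 to
−8), and the probability that adding PFC boosts model evidence does *not*
increase with age (ordinal t = −2.21).  The Bayes-factor table makes the
directional conclusion explicit:

```
                      hypothesis  estimate     se   bf01
        boost increases with age   -1.5306 0.6931 4.8638
PFC-PVC univariate age slope > 0    0.7129 0.2004 0.0058
```

BF01 ≈ 4.9 favours the null over an age-increasing boost — rising
activation without rising information, exactly the dedifferentiation
ground truth this cohort was generated from.  Decodability t ≈ 8 against
the 3-nat criterion confirms the target was decodable throughout (24/24
subjects included).

The same pipeline runs from the shell:

```bash
mvblife all --config run.yaml --out results/
mvblife simulate --config run.yaml --out cohort/   # write a cohort to disk
```

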