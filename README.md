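# dynfnc

Static and dynamic functional network connectivity (FNC) analysis with
connectivity-state clustering and individualized treatment-response
prediction.

## The problem

Resting-state fMRI studies of neuromodulation in the Alzheimer's disease
spectrum ask two questions: *how does treatment reorganize large-scale
brain networks*, and *can a patient's baseline network state predict how
much they will improve?*  The standard analysis decomposes the data into
network components (group ICA), correlates component time courses into a
static FNC matrix, tracks connectivity over tapered sliding windows
(dynamic FNC), clusters windows into recurring connectivity *states* with
dwell-time and transition metrics, compares everything pre/post with
paired tests, and feeds baseline features into a leave-one-out support
vector regression (SVR) to predict each subject's cognitive change score

```
Δcognition_i  ~  SVR_linear( top-m correlation-ranked baseline FNC features ),
R = corr(observed Δ, LOO-predicted Δ),  consensus = ∩_folds top-m selections
```

`dynfnc` implements this full pipeline for researchers who need a tested,
reproducible reference implementation — plus a synthetic cohort generator
that plants known states, treatment effects, and brain–behavior couplings
so that every stage can be validated by recovery of ground truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic cohort (30 subjects × pre/post, 14 components, 230 TRs)
and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_connectivity.py
python analysis/03_state_dynamics.py
python analysis/04_cognition_stats.py
python analysis/05_response_prediction.py
python analysis/06_decomposition_demo.py
```

Selected output (what the scripts actually print):

```
$ python analysis/02_connectivity.py
windows per session: 230 - 30 + 1 = 201
group-mean baseline sFNC (z): rFPN-lFPN 0.529, mVN-pVN 0.238
group-mean change (post - pre): rFPN-lFPN +0.270 (planted +), mVN-pVN -0.267 (planted -)

$ python analysis/03_state_dynamics.py
elbow-selected k = 5 (planted: 5)
state occupancy (fraction of all windows):
  state 1: 13.2%
  state 2: 25.0%
  ...

$ python analysis/04_cognition_stats.py
baseline composite means recomputed from published moments:
  memory         -0.272  (published -0.27)
  visuospatial   -0.064  (published -0.06)
  language       -0.146  (published -0.15)
planted sFNC treatment effects (paired t, p < 0.05 uncorrected):
  rFPN-lFPN: t = -10.33, p = 0.0000, detected
  mVN-pVN: t = +2.81, p = 0.0089, detected

$ python analysis/05_response_prediction.py
LOOCV-SVR prediction of the memory change score, per feature family:
  sfnc         R(best) = +0.730 at m =  2 features; consensus = ['aDMN-pDMN']
  ...
```

Reading this: the planted +0.3/−0.3 correlation changes survive the
pipeline at close to full magnitude (+0.270/−0.267 in Fisher z); the elbow
criterion recovers the five planted connectivity states; pooled pre+post
standardization reproduces the published baseline cognitive composites of
a 28-patient rTMS cohort to two decimals; and baseline sFNC predicts the
simulated memory change score (R = 0.73) with a consensus feature set
drawn from the planted coupling pairs.

The same stages are available as a CLI (`dynfnc run-all --config cfg.yaml
--seed 7`) or as library calls (`dynfnc.run_pipeline(PipelineConfig(...))`),
which also writes a manifest with a parameter hash so that reruns are
byte-identical.

## Layout

```
src/dynfnc/          library: synth, connectivity, states, cognition,
                     prediction, gica, pipeline, cli, benchmarks
analysis/            numbered narrative drivers over the library
scripts/acceptance.py  from-scratch recomputation entry point
tests/               pytest suite (unit, property, end-to-end recovery)
docs/methods.md      model, parameters, design choices, limitations
```
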