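# hyperflux

Kinetic analysis of hyperpolarised ¹³C MRS treatment-response experiments:
two-site-exchange modelling of [1-¹³C]pyruvate→lactate and
[1,4-¹³C₂]fumarate→malate label flux, synthetic spectrum quantification,
and cohort-level response statistics — with a synthetic-data generator that
emulates the cell-suspension and tumour experiments, so the whole pipeline
is testable without scanner data.

## Who this is for

Dynamic nuclear polarisation (DNP) transiently boosts ¹³C NMR signal by
>10⁴, making it possible to watch a single enzyme-catalysed reaction in
live cells or tumours for the ~minute the polarisation survives.  Two
readouts matter for detecting early treatment response:

* **k_P** — the apparent rate constant for hyperpolarised label exchange
  between pyruvate and lactate (lactate dehydrogenase).  Genotoxic drugs
  activate PARP, deplete the NAD(H) pool and slow this exchange: a
  *negative-contrast* response marker.
* **k_F** (or the 20-s malate/fumarate ratio) — fumarate is converted to
  malate by fumarase only once the plasma membrane is compromised, so
  labelled malate is a *positive-contrast* necrosis marker.

This package is for analysts who need to fit these rate constants from
peak-intensity time courses, and for methodologists who want a controlled
synthetic test bed for such fits.

## The model

Longitudinal magnetisation of the substrate/product pair follows the
modified Bloch equations for two-site exchange,

```
d/dt [M_s]   [-(k_fwd + R1s)      k_rev       ] [M_s]
     [M_p] = [   k_fwd        -(k_rev + R1p)  ] [M_p]
```

with R1 = 1/T₁ the relaxation rates that destroy the hyperpolarisation.
Each readout pulse of flip angle θ records `sin θ · M_z` per pool and
leaves `cos θ · M_z`.  The package evaluates the pulse train in closed form
(the scalar cos-losses commute with the linear evolution), and estimates
`k_fwd` (and optionally `k_rev`) plus the initial substrate magnetisation
by multi-start, log-parameterised nonlinear least squares over both
channels jointly, with relaxation rates fixed (k and R1 are not jointly
identifiable from a single bolus).

## Worked example

Simulate an in-vivo acquisition (5° flip, 1 s repetition, 128 transients)
at the untreated-tumour rate constant 0.075 s⁻¹, add 2% noise, and fit:

```python
import numpy as np
from hyperflux import (ExchangeParameters, TUMOUR_SCHEME,
                       simulate_acquisition, TwoSiteExchangeModel)
from hyperflux.model import PeakSeries

params = ExchangeParameters(k_fwd=0.075, m0_sub=15.0)  # 75 mM at ~20% polarisation
traj = simulate_acquisition(params, TUMOUR_SCHEME)
rng = np.random.default_rng(0)
sd = 0.02 * traj.signal_sub[0]
noisy = PeakSeries(traj.times,
                   traj.signal_sub + rng.normal(0, sd, len(traj)),
                   traj.signal_prod + rng.normal(0, sd, len(traj)))
res = TwoSiteExchangeModel(noisy, TUMOUR_SCHEME, mode="unidirectional").fit()
print(res.summary())
```

```
Two-site exchange fit
==============================================
mode:            unidirectional
observations:    240 (both channels, exclusions applied)
converged:       True
residual norm:   9.628e-02 (relative)
----------------------------------------------
parameter         estimate       std err
k_fwd             0.075655      0.000988
m0_sub             14.9901        0.0943
----------------------------------------------
r1_sub           0.0333333   (fixed)
r1_prod          0.0333333   (fixed)
m0_prod                  0   (fixed)
k_rev                    0   (fixed)
```

The fitted `k_fwd` recovers the generating 0.075 s⁻¹ within its ~1×10⁻³
standard error; `m0_sub` is the initial substrate magnetisation in the
same arbitrary units as the input intensities.  (120 of the 128 transients
enter the fit — every sixteenth is acquired from the whole coil volume and
excluded — leaving 240 observations across the two channels.)

Cohort-level analysis runs off the synthetic generator:

```python
from hyperflux import DEFAULT_CELL_SCHEDULE, generate_cohort, build_report
samples = generate_cohort(DEFAULT_CELL_SCHEDULE, n_per_group=4, seed=1)
print(build_report(samples).to_text())
```

which fits every sample and prints group means ± s.d., percent and fold
changes versus untreated, and exact Mann–Whitney p-values (e.g. a 49%
decrease in k_P at 72 h with p = 0.029 at n = 4 per group).

## Command line

```
hyperflux simulate --config run.yaml --out series.csv
hyperflux fit --input series.csv --scheme scheme.yaml --mode unidirectional
hyperflux cohort --config cohort.yaml --out cohort_dir/ --seed 7
hyperflux report --cohort cohort_dir/ --out report.json --text
hyperflux ratio --input spectrum.csv
```

Every run writes a provenance record (config hash, seed, library versions);
identical config + seed gives byte-identical outputs.

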