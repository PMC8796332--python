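# wisn-national

Workload-based staffing-requirement estimation for rural health centres,
from facility activity data to national planning thresholds.

Rural primary and community health centres (PHCs and CHCs) are typically
staffed against fixed per-centre norms that ignore how much work each cadre
actually faces. The WHO's Workload Indicators of Staffing Needs (WISN)
method instead converts a facility's annual service volumes and
per-activity time standards into the number of staff the workload requires.
This package implements a complete WISN analysis pipeline for that setting:

1. **Facility WISN** — for each facility × year × cadre observation,

   ```
   AWT  = [A − (B + C + D + E)] × F          available working time (h/yr)
   HSA  = Σ_s  volume_s / (AWT / unit_time_s)
   CAF  = 1 / (1 − total CAS% / 100)
   IAF  = total IAS / AWT
   WISN = HSA × CAF + IAF
   ```

   with rounding to integer staff and exclusion filters (facilities under
   half a standard 48 h workweek, null WISN values, and nurse records with
   no individual-allowance component).

2. **National thresholds** — facility WISN values are clustered (years
   within facilities, facilities within states). After a Kruskal–Wallis
   check of across-state heterogeneity, a population-averaged log-link
   Poisson model `log E[WISN_ij] = β0 + β1·State + β2·Year` is fitted by
   GEE under independence, exchangeable and AR(1) working correlations;
   the structure with the lowest QIC (Pan 2001) is selected, and the
   marginal mean over the observed state × year design (with a delta-method
   95% CI) becomes the nationally representative per-centre requirement.

3. **Projections** — given state-level in-position staff `P`, sanctioned
   posts `S` and functional centre counts `N`, the per-combo threshold
   `WISN` yields `WISN ratio = P/(WISN·N)`, per-centre and overall WISN
   differences `P/N − WISN` and `P − WISN·N`, sanctioning differences with
   `S` in place of `P`, and their categorical reading (shortage/balance/
   surplus; workload pressure binned from very high to none; under/optimal/
   over-sanctioning).

4. **Agreement** — Spearman rank correlations (pairwise and partial)
   between cadres' state-level WISN ratios detect co-occurring workload
   pressure, and Lin's concordance correlation coefficient measures how
   well sanctioned posts track workload-based requirements (CCC < 0.90 =
   poor agreement).

A synthetic-data module generates facility panels and state staffing tables
with the statistical structure the analysis assumes (negative-binomial
service volumes with state/year/facility effects, unbalanced panels,
configurable under-sanctioning), so the whole pipeline is testable without
access to facility surveys.

## Worked example

Run the numbered analysis scripts in order (or `wisn-national run
--simulate`); each is a thin driver over the library:

```sh
python analysis/01_simulate.py --seed 1      # inputs under results/
python analysis/02_facility_wisn.py
python analysis/03_national_model.py
python analysis/04_projection.py
python analysis/05_agreement.py
```

With seed 1 the facility stage retains 886 of 919 observations (22
partial-workweek and 11 nurse-without-IAS exclusions) and the model stage
prints, e.g.:

```
PHC-nurses: threshold 15 (mean 14.90 [13.69, 16.21], raw 14.934 +/- 0.641, independence, KW p = 0.00261)
CHC-nurses: threshold 45 (mean 45.12 [41.63, 48.91], raw 45.165 +/- 1.860, independence, KW p = 3.18e-05)
PHC-doctors: threshold 2 (mean 1.86 [1.74, 1.98], raw 1.834 +/- 0.055, independence, KW p = 0.00047)
```

i.e. the modelled per-centre requirement is 15 nurses per PHC, 45 per CHC
and 2 doctors per PHC on this panel, each with the QIC-selected working
correlation and the Kruskal–Wallis evidence that averaging over states was
needed. The projection stage then reports, per cadre, national rows such as

```
PHC  nurses   wisn_ratio 0.463   diff_overall −239772   shortage   high   under
```

(a national shortage of ~240 k PHC nurses against the workload-based
requirement at the simulated staffing levels, with high workload pressure
and under-sanctioning), and the agreement stage finds all eight combos
below the 0.90 concordance line — the qualitative signature of sanctioning
norms that do not track workload.

The same stages are available as subcommands: `wisn-national simulate |
wisn | model | project | agree | run | validate` (exit codes 0/1/2 for
ok / validation failure / stage failure).

## Layout

- `src/wisn_national/` — the library: `synthetic` (generators), `wisn`
  (facility arithmetic and exclusions), `national` (Kruskal–Wallis, GEE,
  QIC, marginal means), `projection` (gap metrics and categories),
  `agreement` (Spearman pairwise/partial, Lin's CCC), `pipeline` + `cli`
  (orchestration).
- `analysis/` — the numbered narrative drivers shown above.
- `docs/methods.md` — model assumptions, parameter defaults and
  limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
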