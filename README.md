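# sarcomech

Sarcomere-length mechanics of the left heart: constitutive laws, scenario
sweeps, a reduced closed-loop heart model, and sensitivity / deviation
analytics.

Cardiac muscle force depends on sarcomere length — the Frank–Starling
mechanism.  In the time-varying-elastance (TVE) active-stress law used by
modern cardiac simulators, that dependence enters through two parameters:
the unloaded reference length `L_r` and the threshold length `L_0` below
which no active tension develops.  `sarcomech` is a toolkit for studying
what those two numbers do, for researchers in computational cardiac
biomechanics:

* **Constitutive laws** — the orthotropic Holzapfel–Ogden passive myocardium
  (closed-form biaxial Cauchy stresses, verified against a finite-difference
  energy oracle) and the TVE active law

      σ_af(t, E_ff) = (T_max/2) · Ca0²/(Ca0² + ECa50(E_ff)²) · (1 − cos ω(t, E_ff)),
      ECa50 = Ca0_max / √(exp(B(L − L_0)) − 1),   L = L_r √(2E_ff + 1),

  with the cosine envelope ramping over the time-to-peak `t0` and a
  length-dependent relaxation duration `t_r = mL + b`.
* **Scenario design** — thirteen scenarios perturbing `L_r` (S0 series),
  `L_0` (S1 series), or both at fixed sarcomere-length difference
  SLD = `L_r − L_0` (S2 series) around the control pair (1.85, 1.58) µm.
* **0D surrogate heart** — a closed-loop left heart (TVE-driven spherical
  LV, passive atrium, arterial/venous reservoirs, diode valves) for
  exploring organ-level phenotypes of the scenarios directionally.
* **Analytics** — pump-function metrics (SV, LVEF, CO), percent changes,
  OLS and piecewise sensitivities with the normalised sensitivity
  `S* = (p_base/Y_base)·dY/dp`, strain conversions, and out-of-range
  deviation scores for ranking scenarios against published normal values.
* **Synthetic data** — seeded generators with the statistical structure the
  analytics assume, plus exact closed-form recovery of SLD from peak-stress
  measurements.

The packaged reference data (a 13-scenario metric table with published
normal ranges) makes every stage runnable out of the box.

## Worked example

Two structural facts of the TVE law organise the whole study: the peak
isometric stress depends on the length *difference* only, and the duration
of contraction depends on `L_r` only.  The tissue sweep shows both:

```pycon
>>> from sarcomech import ActiveParams, peak_isometric_stress, duration_of_contraction
>>> peak_isometric_stress(ActiveParams())          # control, SLD = 0.27 um
0.07226569246549781
>>> peak_isometric_stress(ActiveParams(L_r=1.75, L_0=1.48))  # same SLD
0.07226569246549781
>>> duration_of_contraction(ActiveParams())        # t0 + t_r(1.85 um), seconds
0.6114650000000003
```

The peak of 0.0723 MPa is the maximum active fiber stress of an isometric
twitch; it is identical for any scenario with SLD = 0.27 µm, while the
0.611 s duration follows `L_r` alone — increasing `L_r` by 0.1 µm lengthens
contraction by 105 ms.

The analytics reproduce the derived columns and sensitivities of the
reference metric table from its EDV/ESV values:

```pycon
>>> from sarcomech.metrics import (load_printed_metric_table,
...     series_sensitivity_table, deviation_table, rank_scenarios)
>>> table = load_printed_metric_table()
>>> sens = series_sensitivity_table(table).set_index(["series", "metric"])
>>> sens.loc[("S0", "EDV_mL")][["slope", "S_star", "R2"]].astype(float).round(3)
slope    -53.300
S_star    -0.691
R2         0.987
Name: (S0, EDV_mL), dtype: float64
>>> rank_scenarios(deviation_table(table))[:3]
['S21', 'S11', 'S22']
```

End-diastolic volume falls by 53.3 mL per µm of `L_r` across the S0 series
(normalised sensitivity −0.69, R² 0.987), and the summed out-of-range
deviation score identifies S21 and S11 — the two scenarios with shortened
`L_0` — as the most abnormal cases.

A command-line interface wraps the same stages:

```sh
sarcomech --outdir out verify        # passive + active verification, exit 0 on PASS
sarcomech --outdir out sweep         # 13-scenario tissue summary CSV
sarcomech --outdir out surrogate     # 0D closed loop, all scenarios
sarcomech --outdir out sensitivity   # global + piecewise sensitivity tables
sarcomech --outdir out rank          # deviation scores and ranking
```

## Layout

```
src/sarcomech/
  passive.py       Holzapfel–Ogden passive law + biaxial closed forms + oracle
  active.py        TVE active law (ECa50, activation phase, twitch summaries)
  verification.py  unit-state verification reports
  scenarios.py     13-scenario table and tissue sweeps
  surrogate.py     0D closed-loop left heart
  metrics.py       metrics, sensitivities, deviation scores, strain conversion
  synth.py         seeded generators + SLD/slope recovery
  io.py, cli.py    CSV/config I/O and the `sarcomech` command
  data/            packaged reference table, normal ranges, default parameters
docs/methods.md    model documentation, numerical choices, known limitations
```

The surrogate is an intentionally reduced, homogeneous model: its
organ-level claims are directional sign patterns, not quantitative
hemodynamics; `docs/methods.md` documents which published phenotypes it
reproduces and which it structurally cannot.
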