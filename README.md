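# edwarn — prospective ED crowding early warning

Emergency-department (ED) crowding is consistently associated with worse
patient outcomes, and the administrative countermeasures (calling in staff,
pushing patients to follow-up care) act with hours of delay. A forecasting
system that can flag, during the morning, that *this afternoon* will be
crowded turns those reactive manoeuvres into proactive ones.

`edwarn` is a desk-scale implementation of such a system, aimed at
biostatisticians and ED operations researchers. It provides:

* **Hourly Holt-Winters forecasters** of ED arrivals and occupancy — the
  additive (AHWM), multiplicative (MHWM) and damped (HWDM) seasonal
  variants with daily cycle m = 24, fitted by maximum likelihood
  (equivalently least squares on one-step residuals):

  ```
  l_t = α (y_t − s_{t−m}) + (1−α)(l_{t−1} + b_{t−1})
  b_t = β (l_t − l_{t−1}) + (1−β) b_{t−1}
  s_t = γ (y_t − l_{t−1} − b_{t−1}) + (1−γ) s_{t−m}
  ŷ_{t+k} = l_t + k·b_t + s_{·}          (damped: k → φ + … + φᵏ)
  ```

* a **prospective rolling-origin harness**: every hour, train on all
  history available at the origin (strictly no lookahead), emit 24 hourly
  point forecasts into an append-only prediction store, keep running
  through gaps and fitting failures;
* a **quartile crowding definition**: a day is crowded when its daily peak
  occupancy (DPO) is in the top quartile; the operative threshold θ is the
  nearest-rank 75th percentile of DPOs, an hour is crowded when
  occupancy ≥ θ, a 24-h window when any of its hours is;
* **binary early-warning evaluation**: Mann-Whitney AUC (midrank ties) with
  class-balanced downsampling and 250-iteration percentile-bootstrap CIs,
  reported per horizon (PPH), per origin hour (PPO), and as a 24×24
  origin × horizon AUC matrix, plus MAE/RMSE and threshold metrics
  (sensitivity, specificity, F1);
* a **synthetic ED generator** — nonhomogeneous Poisson arrivals with a
  calibrated diurnal profile, i.i.d. log-normal afternoon surge multipliers,
  and an infinite-server queue with log-normal lengths of stay producing
  occupancy — so the entire pipeline is reproducible without patient data.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```
$ edwarn simulate -c config.yaml      # 60 synthetic days, seeded
wrote arrivals.csv and occupancy.csv (1440 rows each)
$ edwarn forecast -c config.yaml      # prospective run, 14-day warm-up
store: 105888 records (+105888); 0 skipped origins
$ edwarn evaluate -c config.yaml
reports in reports/ (theta=86, 1104 prediction rows lacked actuals)
```

The store holds 2 models × 2 targets × 1103 hourly origins × 24 horizons.
The crowding threshold derived from this run is θ = 86 patients. From the
report tables (additive model, 46 evaluation days):

| quantity | value | reading |
|---|---|---|
| arrivals MAE / RMSE | 2.51 / 3.29 | hourly arrival counts are predictable to ~2.5 patients |
| occupancy MAE / RMSE | 9.57 / 12.77 | occupancy to ~10 patients |
| PPH AUC t+1 / t+24 | 1.00 / 0.82 | next-hour crowding is near-perfectly ranked; skill degrades with horizon |
| PPO AUC at 00:00 | 0.53 (CI 0.28–0.79) | at midnight the coming day's crowding is unpredictable — the generator's day surges are independent of history |
| PPO AUC at 15:00 | 0.87 | by mid-afternoon the surge is partially realized and the warning becomes actionable |

Programmatic use follows the model/results convention:

```python
>>> import edwarn as ew
>>> arr, occ = ew.simulate_ed(60, seed=1)
>>> res = ew.HoltWinters(occ, variant="damped", seasonal_periods=24).fit()
>>> print(res.summary())
Holt-Winters Smoothing Results
==============================================
variant:              damped (HWDM)
seasonal period:      24
nobs:                 1440
train end:            2022-03-01 23:00:00
log-likelihood:       -4103.10
----------------------------------------------
alpha (level):        0.9782
beta (trend):         0.0000
gamma (seasonal):     0.0878
phi (damping):        0.8000
sigma2 (resid var):   17.4767
==============================================
>>> res.forecast(3).round(1).tolist()
[60.0, 56.8, 54.4]
```

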