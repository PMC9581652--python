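# bayar — Bayesian AR forecasting for monthly outpatient-visit series

Hospitals plan staffing, beds and procurement around the number of patients
who will walk through the outpatient door next month. Multi-year monthly
visit registers share a characteristic shape: a slowly rising level, a strong
annual cycle (mid-summer peak, January–February trough), autocorrelated
noise, and the occasional abrupt pattern change. `bayar` is a small toolkit
for forecasting such series with an autoregressive model fitted two ways — by
classical least squares and by Bayesian inference via Gibbs sampling — and
for quantifying forecast uncertainty with a fan of prediction intervals.

## The model

The order-p autoregression treats each month as a noisy linear combination of
the p preceding months:

    y_t = α + Σ_{k=1..p} β_k y_{t−k} + ε_t,   ε_t ~ N(0, σ²)

**Baseline fit.** Conditional least squares on the lag-trimmed sample. The
lag order is chosen by minimizing

    AIC(p) = log(SSE_p / (T − p)) + (T − p + 2p) / (T − p)

over p = 1 … T/2 (T the training length, SSE the residual sum of squares,
natural log), with a stationarity screen that excludes fits whose
characteristic roots 1 − Σ β_k z^k fall on or inside the unit circle.

**Bayesian fit.** Independent N(0, 1) priors on α and each β_k and an
inverse-gamma(1/2, 1/20) prior on σ². Both priors are conditionally
conjugate, so a systematic-scan Gibbs sampler draws each parameter in turn
from its exact full conditional (Normal for coefficients, inverse-gamma for
σ²); 20,000 iterations with the first 4,000 discarded as burn-in give 16,000
retained posterior draws. No stationarity constraint is imposed — dropping
the stability screen is what lets the lag order rise to 12+ and capture the
annual cycle.

**Forecasts and intervals.** Each retained draw is propagated recursively
over the horizon (adding fresh N(0, σ²) process noise by default), giving
16,000 forecast trajectories. The per-month sample mean is the point
forecast, the SD its uncertainty, and empirical quantiles form 17 central
prediction intervals at levels 0.10, 0.15, …, 0.90. Accuracy is scored
against the held-out final 20% of the series by RMSE and MAPE (percent).

Because no suitable public register ships with the package, a synthetic-data
module generates hospital-like series (trend + peaked annual cycle + AR noise
+ optional late-series level shift) and drives all calibration harnesses.

## Worked example

```
bayar simulate --out series.csv --seed 42                 # 120 months, ~2e5 visits/month
bayar evaluate --input series.csv --mode compare --order 12 \
      --iterations 20000 --burn-in 4000 --seed 1 --out compare.csv
cat compare.csv
```

```
model,order,rmse,mape
AR,12,10333.699732624707,3.1063903194918407
BayesianAR,12,6949.763217364406,2.2562744208286922
```

Both models were trained on the first 96 months and forecast the final 24 in
one shot. The AIC-screened least-squares baseline lands at order 12 and
misses by 3.11% on average (RMSE ≈ 10,334 visits); the Bayesian AR(12)
posterior-predictive mean misses by 2.26% (RMSE ≈ 6,950 visits) — the
Bayesian fit averages over parameter uncertainty instead of committing to
one estimate, which stabilizes the long recursive forecast.

The full pipeline is also available piecewise:

```
bayar bayes-fit --input series.csv --order 12 --iterations 20000 \
      --burn-in 4000 --seed 1 --draws-out draws.tsv
bayar forecast --draws draws.tsv --input series.csv --horizon 12 \
      --seed 1 --out forecast.csv        # point, sd, l10..l90 interval pairs
bayar diagnose --input series.csv        # kurtosis, skewness, permutation entropy
bayar evaluate --input series.csv --mode stability --order 12 ... # MAPE vs training share
```

`diagnose` on the simulated series prints, e.g., kurtosis 2.47 and
permutation entropy 2.52 nats (embedding dimension 4) — light-tailed and
moderately complex, typical of a strongly seasonal register.

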