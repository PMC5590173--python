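# mmtmc — Monte Carlo estimation of the minimum mortality temperature

`mmtmc` estimates the **minimum mortality temperature (MMT)** — the
temperature at which the lag-cumulated temperature–mortality risk curve
attains its minimum — together with honest uncertainty intervals, from daily
time series of death counts and mean temperature.  It is aimed at
environmental epidemiologists and biostatisticians who fit distributed lag
nonlinear models (DLNMs) to city-level mortality data and need point and
interval estimates both for the MMT itself and for cold-/heat-related
relative risks that use the MMT as reference.

## The model and estimators

Daily deaths are modelled by a quasi-Poisson time-series regression

    Y_t ~ quasi-Poisson(mu_t)
    log mu_t = alpha + s(x_t; eta) + sum_j h_j(u_jt; gamma_j)

where `s()` is a DLNM cross-basis in temperature and lag (quadratic B-spline
in temperature, natural cubic spline in lag, or a plain moving-average
metric as the one-column special case), and the confounder terms are
day-of-week indicators plus a natural cubic spline of calendar time with 8
df per year.  Cross-basis coefficients are reduced to the lag-cumulated
coefficients `beta = M eta`, `V(beta) = M V(eta) M'` with
`M = 1'C (x) I`, and the curve at temperature `x` is `Q_x beta`.

Four MMT estimators operate on the reduced fit:

| method | estimate |
|---|---|
| `Argmin1` | grid argmin of `Q_x beta-hat` over the observed range (point only) |
| `Argmin2` | the same, constrained to the 1st–99th observed temperature percentiles |
| `Empirical1` | approximate parametric bootstrap: `beta_(i) ~ MVN(beta-hat, V(beta-hat))`, `theta_(i) = argmin_x Q_x beta_(i)`; empirical mean and 2.5th–97.5th percentiles |
| `Empirical2` | the same proposals filtered through a Uniform(alpha1, alpha2) prior on the MMT (rejection sampling), yielding a posterior MMT distribution |

For a highly right-skewed MMT distribution the interval's percentile pair
can be switched to the skew-adjusted (0th, 95th).  Relative risks comparing
the 1st/99th temperature percentiles to the MMT are computed either against
a fixed MMT point estimate (delta-method normal CI) or with the MMT
uncertainty propagated per draw: `RR_(i) = exp((Q_x − Q_theta(i)) beta_(i))`.

A simulation harness generates synthetic multi-year series under four true
association shapes (U, reverse-J, rotated-S, sector) with known true MMTs,
and scores estimators by bias, RMSE, coverage probability and mean interval
length.

## Worked example

Fit a synthetic 5-year series (generated by the package's own U-shape
scenario, true MMT 23.889 °C) with a 3-day moving-average temperature
metric:

```bash
mmtmc estimate series.csv --config config.yaml --out results/
```

with `config.yaml`:

```yaml
moving_average_window: 3
n_sim: 2000
methods: [Argmin2, Empirical1, Empirical2]
prior_support: [1, 99]
seed: 1
```

`results/estimates.csv` (values from an actual run):

```
method,mmt_point,mmt_lo,mmt_hi,n_proposed,n_accepted,cold_rr,...
Argmin2,20.832,,,0,0,1.107,...
Empirical1,20.480,11.532,32.318,2000,2000,1.113,...
Empirical2,19.995,11.532,26.532,2087,2000,1.112,...
```

Reading: the constrained argmin point estimate is 20.8 °C; the unrestricted
Monte Carlo MMT distribution (2000 draws) has mean 20.5 °C with a 95%
empirical interval of (11.5, 32.3) °C; restricting the prior support to the
1st–99th temperature percentiles keeps 2000 of 2087 proposals and shortens
the interval to (11.5, 26.5) °C without moving the point much.  Cold-related
RRs (1st percentile vs MMT) are ~1.11 under all three methods.  A single
5-year replicate identifies the MMT only loosely — that is precisely the
uncertainty the intervals quantify.

The `simulate` subcommand runs the replicated scenario studies
(`mmtmc simulate --scenario U --out out/`), and `curves` dumps the fitted
curve and empirical MMT density for plotting.

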