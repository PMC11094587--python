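# edmcast

Simplex projection and S-map forecasting on delay-embedded time series, with
explicit focal-point validity rules and candidate-neighbour-library
bookkeeping.

A univariate series `N_t` (t = 1..T) is first-differenced
(`Y_t = N_{t+1} − N_t`, switchable off), embedded in an E-dimensional state
space of lagged values, and predictions are made from where a focal point's
nearest state-space neighbours moved one step later (simplex), or from a
locally weighted linear map over the whole candidate library (S-map).  The
package makes two usually-implicit pieces of bookkeeping first-class:

* **valid focal times** — `{E..T−2}` for evaluation, `{E..T−1}` for
  forecasting (shifted automatically when differencing is off);
* **the library** of candidate neighbours for each focal time `t*`, after
  excluding (a) the focal point, (b) rows with undefined lags, (c) rows with
  unknown successors, and (d) rows containing the value being predicted —
  with a closed-form size `T − 2(E+1)` in the constant region, climbing by 1
  per step over the last E focal times.  A temporal-radius alternative to
  (d) (`radius:k`) matches other toolkits' exclusion-radius behaviour.

Every prediction exposes its intermediate quantities (neighbour times,
distances, weights) so independent implementations can be diffed cell by
cell.

## CLI

```sh
edmcast generate --kind spiky --T 100 --seed 42 -o series.csv
edmcast library --T 50 --E 2 --tstar 10            # member times + size
edmcast library-grid --T 50 --Emax 8 -o grid.csv   # size table over (t*, E)
edmcast simplex --input series.csv --E 3 [--tstar 39] [--policy radius:0]
edmcast smap --input series.csv --E 3 --theta 0 --theta 2
edmcast evaluate --input series.csv --Emin 2 --Emax 6 [--common-tstar]
edmcast forecast --input series.csv --E 3 [--remedy none|clamp|log]
edmcast run --config run.yaml                      # full pipeline
```

`run` writes `per_E.csv`, `predictions.csv`, `neighbours.csv` (full
bookkeeping), `forecast.json` and `run.log` into the output directory.
Data files are full double precision; policies are `default` or `radius:k`.

## Library API

```python
import edmcast as e

series = e.generate_spiky_series(e.SpikySeriesConfig(seed=42))
result = e.select_E(series, range(2, 7))          # leave-one-out rho per E
fc = e.forecast_next(series, result.E_star)       # one step past the data
print(result.E_star, fc.y_hat, fc.n_hat)
```

Lower-level pieces: `first_difference`, `build_lag_matrix`,
`valid_focal_times`, `construct_library` / `library_size`,
`rank_neighbours`, `simplex_weights`, `predict_point`, `pearson_rho`,
`smap_predict` / `theta_scan`, and multivariate embeddings via
`CoordinateSpec` + `MultivariateEmbedding` (library rules generalise with
the maximum lag `m`: E is replaced by `m+1` everywhere).

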