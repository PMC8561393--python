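# colonychirality

Quantification of **colony-scale chirality** in bacterial range
expansions, plus the single-cell measurements that accompany it:
twist-recovery rates from TIRF photobleaching assays, filamentation
statistics from colony-edge samples, and maximal growth rates from
OD600 curves.

## The scientific problem

When a mixed drop of two differently labelled but otherwise identical
*E. coli* strains grows into a colony, genetic drift at the expanding
front demixes the population into single-colour sectors — a pinwheel
pattern whose sector boundaries are a frozen record of growth. For many
strains the boundaries do not run radially: they bend systematically
clockwise (viewed from the air interface), and are well described by
**logarithmic (equiangular) spirals**,

    phi(r) = phi_0 + tan(theta) * ln(r / r_i),

where `r_i` is the homeland (inoculum) radius and `theta` is the
**chiral angle**, the constant angle between the boundary and the
radial direction. `theta` is the quantitative readout of colony
chirality; untreated DH5α colonies show `theta ≈ 6.4°`, and
perturbations (MreB depolymerisation by A22, anaerobic growth,
temperature, division inhibition by cephalexin) move it.

The package implements the full measurement chain:

1. **`synthetic`** — generators with known ground truth: pinwheel
   colonies (spiral boundaries + Brownian wander, rasterised to
   two-channel 16-bit images), linear fluorescence-recovery curves,
   bimodal cell-length samples, logistic growth curves.
2. **`boundary`** — boundary extraction from a YFP/CFP image pair:
   normalised difference image, Laplacian-of-Gaussian zero-crossing
   edge detection, least-squares circle fit of the colony centre, polar
   transform, nearest-neighbour chaining into traces, radius/shape
   filtering, scripted curation, smoothing.
3. **`chirality`** — the estimator: traces from all colonies of a
   condition are pooled; per radial bin, each trace contributes a local
   slope `dphi/d ln r`; a 200-iteration bootstrap over traces averages
   the slopes and integrates them over `ln r` into a **mean rotation
   curve** `phi(r)` with `phi(r_i) = 0`; the chiral angle is
   `theta = arctan(slope)` of that curve over a radial fit window.
   Exposed as `ChiralityModel(...).fit() -> ChiralityResults`.
4. **`twist`** — prebleach-normalised recovery curves, the recovery
   rate `lambda` (OLS slope over the first 3 um of elongation), and a
   quadrant-asymmetry handedness call. Exposed as
   `TwistRateModel(...).fit() -> TwistRateResults`.
5. **`phenotype`** — cell-length summaries (fraction of cells longer
   than 5 um, ECDF), density-stratified comparisons, KS/Mann-Whitney
   reports, and the maximal slope of `ln(OD)` over 11-point sliding
   windows.

## Worked example

```python
import colonychirality as cc

# a synthetic colony with known chirality (6.4 deg, with boundary wander)
spec = cc.SyntheticColonySpec(theta_true=6.4, seed=1)
pair = cc.render_colony(cc.generate_boundaries(spec), spec)

# extract sector-boundary traces and fit the chiral angle
ts = cc.extract_traces(pair, colony_id="demo")
res = cc.ChiralityModel(ts).fit(n_boot=200, seed=1, window=(1200, 2700))
print(res.summary())
```

```
Chiral-angle fit (bootstrap over pooled traces)
================================================
traces pooled                  20
colonies                        1
radial bins                    50
bootstrap iterations          200
fit window             [1200.0, 2700.0]
slope dphi/dln(r)         0.10643
chiral angle theta          6.075 deg
bootstrap sd                0.974 deg
sign: positive = clockwise viewed from the top
```

All 20 boundaries were recovered from the rendered image and the fitted
angle (6.08° ± 0.97° bootstrap spread) agrees with the generating 6.4°
within the wander noise of a single colony; averaging over ~10 colonies
pins the mean to well within a degree. `res.plot()` draws the mean
rotation curve with its bootstrap band and the window fit.

The same pattern applies to twist data:

```python
curve = cc.generate_twist_curve(cc.TwistSimSpec(lambda_true=0.1,
                                                noise_sd=0.05, seed=2))
print(cc.TwistRateModel(curve).fit(dl_fit=3.0).summary())
# -> lambda (1/um)  0.10337   (true rate 0.1/um)
```

A `colonychirality` command-line tool wraps the stages
(`simulate`, `trace`, `chirality`, `twist`, `filament`, `growth`); see
`colonychirality --help`.

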