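# betabreak

Tools for asking whether a *threshold* in climate history — rather than a
smooth contemporary gradient — shapes present-day patterns of compositional
variation in species assemblages.

Large-scale beta diversity mixes two antithetical phenomena: **spatial
turnover** (species replacing one another between sites) and **nestedness**
(poor sites holding subsets of rich sites' species).  `betabreak` computes
the additive Sørensen-family partition on a 1°×1° presence/absence grid
aggregated into ~250,000 km² regional cells, then hunts for a latitudinal
breakpoint separating a turnover-dominated from a nestedness-dominated
world, and relates both components to present climate, glacial-age climate
and topography with inference that respects spatial autocorrelation.

## The statistics at its core

For sites with richness $S_i$, pooled richness $S_T$ and $b_{ij}$ species
present in site $i$ but not $j$, with $P=\sum_i S_i - S_T$,
$\Sigma_{\min}=\sum_{i<j}\min(b_{ij},b_{ji})$ and
$\Sigma_{\max}=\sum_{i<j}\max(b_{ij},b_{ji})$:

$$\beta_{SIM}=\frac{\Sigma_{\min}}{P+\Sigma_{\min}},\qquad
\beta_{SOR}=\frac{\Sigma_{\min}+\Sigma_{\max}}{2P+\Sigma_{\min}+\Sigma_{\max}},\qquad
\beta_{NES}=\beta_{SOR}-\beta_{SIM}.$$

Per region the triple is averaged over repeated subsamples of 15 cells (10
replicates) to standardize for region size.  Each response is regressed on
absolute centroid latitude with a continuous broken stick,
$y\sim 1+x+(x-bp)\,\mathbb{1}[x>bp]$, the breakpoint found by exhaustive
1°-interval search minimizing residual standard error and tested against
the straight line with $F\big((RSS_{lin}-RSS_{pw})/2,\;RSS_{pw}/(n-4)\big)$
on $(2,\,n-4)$ degrees of freedom.  Correlations between beta components
and environment use the modified t-test for spatially autocorrelated data
(effective sample size
$\hat M = 1 + \mathrm{tr}(HA)\,\mathrm{tr}(HB)/\mathrm{tr}(HAHB)$
built from distance-class Moran estimates of the autocorrelation matrices
$A$, $B$), and
explained variation is split into unique and shared fractions by partial
regressions.  A synthetic-world generator provides grids and climate
surfaces with a known breakpoint so every stage can be validated against
ground truth.

## Worked example

`examples/06_full_study.py` runs the complete study on a noiseless
synthetic world whose regimes switch at the 37th parallel:

```
regions retained: 188
beta_sor: breakpoint   34, slopes +0.0002/-0.0171, F(2,184) = 130.6; means 0.951 below / 0.735 above
beta_sim: breakpoint   37, slopes +0.0004/-0.0384, F(2,184) = 561.2; means 0.950 below / 0.523 above
beta_nes: breakpoint   44, slopes +0.0005/+0.0292, F(2,184) = 804.2; means 0.005 below / 0.252 above
   t_dif: breakpoint   37, slopes +0.0900/+0.2400, F(2,184) = inf; means 3.643 below / 8.053 above
  t_pres: breakpoint    4, slopes -0.4500/-0.4500, F(2,184) = 0.0; means 26.650 below / 14.590 above
     pet: breakpoint    4, slopes -18.0000/-18.0000, F(2,184) = 0.0; means 1546.000 below / 1063.600 above
glaciated contrast (beta_sim): U = 38.0, p = 3.53e-10 (26 glaciated vs 39 not)
glaciated contrast (beta_nes): U = 16.0, p = 5.1e-11 (26 glaciated vs 39 not)
```

Reading it: the turnover component and the present-minus-glacial
temperature anomaly both break exactly at latitude 37 (the generator's
truth) — T_DIF perfectly (infinite F, the surface is noiseless), the smooth
surfaces T_PRES and PET show no breakpoint at all (F = 0; the reported
candidate is just the tie-break minimum).  Turnover dominates equatorward
of the breakpoint (mean β_SIM 0.95 vs 0.52), nestedness poleward (β_NES
0.005 vs 0.25), and within the poleward zone glaciated regions are more
nested and less turnover-rich than unglaciated ones.

The other examples each demonstrate one capability: the partition on a
three-site toy matrix (01), the synthetic world itself (02), breakpoint
search under noise (03), why the spatial correction is needed — the naive
test rejects 49% of independent autocorrelated pairs, the corrected one 4%
(04) — and variance partitioning with collinear predictor groups (05).

There is also a thin CLI: `betabreak synth|beta|breakpoint|cortest|varpart|run`
(see `betabreak --help`).

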