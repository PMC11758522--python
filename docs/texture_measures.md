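# Areal texture measures

All measures operate on the mean-subtracted grayscale height field
`z(r, c)` of one cementum patch (grayscale treated as height; pixel
units).  `N` is the pixel count, `Sq` the RMS height.

## Amplitude

| name | definition |
|------|------------|
| `sa` | arithmetic mean height, `mean(|z|)` |
| `sq` | RMS height, `sqrt(mean(z²))` |
| `ssk` | skewness, `mean(z³)/Sq³` (NaN for a flat patch) |
| `sku` | kurtosis, `mean(z⁴)/Sq⁴` (NaN for a flat patch) |
| `sp` | maximum peak height, `max(z)` |
| `sv` | maximum valley depth, `−min(z)` |
| `sz` | total height range, `sp + sv` |

## Spatial

The normalized 2-D autocorrelation `ACF(Δr, Δc)` is computed by FFT.
Along 72 directions through the origin the decay length is the first
radius at which the ACF falls below `1/e`.

| name | definition |
|------|------------|
| `sal` | autocorrelation length: the *shortest* per-direction decay length |
| `str` | texture aspect ratio: shortest / longest decay length, in [0, 1]; near 0 for strongly banded (anisotropic) texture, near 1 for isotropic noise |
| `std` | dominant texture direction (degrees, [0, 180)): perpendicular to the highest-power non-DC spatial frequency; 0° = bands parallel to the circumferential axis |

## Hybrid

With `(gx, gy)` the numerical gradient of `z`:

| name | definition |
|------|------------|
| `sdq` | RMS surface gradient, `sqrt(mean(gx² + gy²))` |
| `sdr` | developed interfacial area ratio, `mean(sqrt(1 + gx² + gy²) − 1)` |

## Functional (bearing curve)

`c(p)` is the Abbott-Firestone curve: height as a function of material
ratio `p ∈ [0, 1]` (heights sorted descending).  The flattest 40%-wide
secant of `c` is extended to `p = 0` and `p = 1`, giving core bounds
`y0 > y1`:

| name | definition |
|------|------------|
| `sk` | core height, `y0 − y1` |
| `spk` | reduced peak height: `2·A1/smr1`, `A1` the area of `c` above `y0` |
| `svk` | reduced valley depth: `2·A2/(1 − smr2)`, `A2` the area below `y1` |
| `smr1` | material ratio where `c` crosses `y0` |
| `smr2` | material ratio where `c` crosses `y1` |

Material/void volumes are bearing-curve integrals at the conventional
10% / 80% ratios, `Vm(p) = ∫₀^p max(c(q) − c(p), 0) dq` and
`Vv(p) = ∫_p^1 max(c(p) − c(q), 0) dq`:

| name | definition |
|------|------------|
| `vmp` | peak material volume, `Vm(0.10)` |
| `vmc` | core material volume, `Vm(0.80) − Vm(0.10)` |
| `vvc` | core void volume, `Vv(0.10) − Vv(0.80)` |
| `vvv` | valley (dale) void volume, `Vv(0.80)` |
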