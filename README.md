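# msdeconv

Deconvolution and compensation of **overlap (isobaric) interferences** in
quadrupole mass-spectrometric gas analysis.

Portable quadrupole MS systems quantify environmental gases (He, Ne, Ar,
N2, O2, CH4, CO2, ...) by *peak-height comparison*: the ion current at a
species' m/z is ratioed against a reference gas of known composition.
That fails when several species feed the same peak — N2 fragments and O2
interfere with the CH3+ fragment used for CH4 at m/z 15; 40Ar++ and
20(H2O)+ interfere with 20Ne at m/z 20. msdeconv is for lab and field
users of such instruments who cannot avoid these interferences and need to
remove them in data processing.

## Method

A measured spectrum of peak heights y(mu_j) +/- dy(mu_j), j = 1..M, from a
single detector is modelled as a linear combination of N <= M
max-normalized basis spectra x_i (one per species, measured once on the
same instrument):

    y~(mu_j) = sum_i a_i x_i(mu_j)

The amplitudes a_i minimize the error-weighted residual sum
chi2 = sum_j ((y~(mu_j) − y(mu_j)) / dy(mu_j))², with dy floored at 1% of
y (the instrument's typical relative accuracy) and coefficient errors
inflated by sqrt(chi2/chi2_sigma) when chi2 exceeds its 1-sigma quantile.
The target species' share of the current at the target m/z,
f = a_t x_t(mz) / sum_k a_k x_k(mz), is then the only part used in the
calibration:

    c_sample = (f_s y_s) / (f_r y_r) * c_reference

See `docs/methods.md` for the full model, error propagation and design
choices.

## Worked example

Two validation campaigns are bundled (`msdeconv.datasets`). In the neon
campaign, three test gases were measured on the electron multiplier at
m/z 17, 20, 36 and deconvolved against H2O, 20Ne and Ar basis spectra;
Gas-III (dry synthetic air with a 326 ppm 20Ne spike) serves as reference
for Gas-V (atmospheric air with an Ar spike, 15.8 ppm 20Ne nominal):

```python
from msdeconv import fit_coefficients, ion_current_fractions, compensate, calibrate
from msdeconv.datasets import neon_example

ds = neon_example()
for gas in ("Gas-III", "Gas-V"):
    fit = fit_coefficients(ds.gases[gas], ds.block.basis)
    ft = ion_current_fractions(fit, ds.block.basis, 20)
    f, df = ft.fraction("Ne")
    print(f"{gas}: Ne fraction at m/z 20 = {100*f:.1f} +- {100*df:.1f} %")

ref = compensate(ds.gases["Gas-III"].peak(20),
                 ion_current_fractions(fit_coefficients(ds.gases["Gas-III"], ds.block.basis),
                                       ds.block.basis, 20), "Ne")
smp = compensate(ds.gases["Gas-V"].peak(20),
                 ion_current_fractions(fit_coefficients(ds.gases["Gas-V"], ds.block.basis),
                                       ds.block.basis, 20), "Ne")
amount = calibrate(smp, ref, 326.0, reference_label="Gas-III")
print(f"compensated 20Ne in Gas-V: {amount.value:.1f} +- {amount.dvalue:.1f} ppm")
```

prints

```
Gas-III: Ne fraction at m/z 20 = 73.8 +- 0.4 %
Gas-V: Ne fraction at m/z 20 = 14.6 +- 1.2 %
compensated 20Ne in Gas-V: 16.9 +- 1.4 ppm
```

Only 14.6% of the m/z 20 current in Gas-V is actually neon — the rest is
water vapour (and a trace of 40Ar++). Raw peak-height comparison would
report 86 ppm, more than five times the true value; after compensation the
result (16.9 +/- 1.4 ppm) agrees with the nominal 15.8 ppm.

## Command line

```
msdeconv deconv sample.txt             # aggregate + deconvolve one analysis step
msdeconv calibrate --sample s.txt --standard r.txt --amount CH4=231000
msdeconv simulate scenario.yaml -o readings.txt --seed 7
msdeconv validate                      # re-run the bundled validation campaigns
```

Readings files are plain text (one `PEAK`/`ZERO` reading per line) and may
embed single-line `DECONVOLUTION:` configuration records; both formats are
documented in `docs/methods.md`.

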