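# paragest

**Lanthanide sensing by ¹⁹F saturation-transfer fingerprinting.**

A fluorinated guest molecule in aqueous solution exchanges between its free
state and the cavity of lanthanide-chelating α-cyclodextrin hosts
(Ln-α-CD). Each lanthanide's pseudocontact shift places the bound-guest
¹⁹F resonance at a characteristic offset Δω (spanning ~45 ppm across the
series), and selective saturation of a bound pool is transferred to the
free pool by guest exchange (GEST, a supramolecular variant of CEST). This
package implements the complete computational side of a
fingerprinting-based sensing workflow:

1. **Simulation** — multi-pool Bloch–McConnell dynamics propagated exactly
   by matrix exponentials, producing z-spectra and 40-point fingerprint
   trajectories for arbitrary host mixtures.
2. **Dictionary** — combinatorial enumeration of mixture hypotheses
   (subset of lanthanides × concentration grid) and bulk simulation of one
   fingerprint per hypothesis, stored as a chunked HDF5 container.
3. **Matching** — cosine-similarity pattern recognition of a measured (or
   synthetic) fingerprint against all dictionary entries, with an R²
   fidelity report of the best match.
4. **Parameter extraction** — joint nonlinear least-squares fitting of
   multi-power z-spectra to recover (T₁, T₂, Δω, f, k_ex) per host–guest
   pair.
5. **Synthetic data** — a 14-member synthetic parameter library and a
   seeded noise model so every stage is testable without a spectrometer.

## The model

For a free pool (index 0) and N bound pools in star topology, the
magnetization in the frame rotating at the saturation frequency obeys

    dMx_p/dt = −Mx_p/T2_p + Δ_p·My_p
    dMy_p/dt = −Δ_p·Mx_p − My_p/T2_p + ω₁·Mz_p
    dMz_p/dt = −ω₁·My_p − (Mz_p − M0_p)/T1_p

plus exchange terms on all three components, with forward rate
k_f,i = f_i·c_i·k_ex,i (free → bound i) and reverse rate k_ex,i. Here
Δ_p = δ_p − ω_rf is the offset in rad/s, ω₁ = γB₁ the nutation frequency,
M0_free = 1 and M0_bound,i = f_i·c_i. Augmenting the state with a constant
1 makes the system homogeneous, so each saturation or recovery interval is
the exact linear map exp(A·t).

The default acquisition protocol has 40 points in three blocks: the 14
characteristic offsets plus a +200 ppm reference at 1.75 μT (points 1–15),
the same offsets at 2.87 μT (16–30), and ten offsets sweeping 1–11 ppm at
2.87 μT with shorter saturation (31–40), all separated by 9.57 s recovery.
A fingerprint is the free-pool Mz trajectory over those points, carried
sequentially through every delay and pulse, normalized to the reference
point.

## Worked example

```python
import numpy as np
import paragest as pg

library = pg.default_library()                       # 14 synthetic Ln pairs
protocol = pg.build_default_protocol(library.offsets)

# A "measured" Dy+Nd mixture with sigma = 0.005 noise
sample = pg.generate_sample(["Dy", "Nd"], [1.0, 1.0], library)
fp = pg.generate_noisy_fingerprint(sample, protocol, pg.NoiseModel(0.005, seed=7))

# Dictionary over all 1- and 2-member mixtures, 3-level concentration grid
d = pg.build_dictionary(library, {1, 2}, [0.5, 1.0, 2.0], protocol)
print(len(d))

res = pg.match(fp, d, top_k=3)
print(res.best.label(), round(res.best_score, 5), round(res.fidelity_r2, 4))
```

prints

```
861
Dyx1+Ndx1 0.99999 0.9997
```

i.e. the dictionary holds 14·3 + 91·9 = 861 entries, the rank-1 hit is the
generating hypothesis (Dy and Nd, both at unit concentration) with cosine
score 0.99999, and the matched simulated fingerprint explains the noisy
input with R² = 0.9997.

The same workflow is available from the shell:

```bash
paragest gen --subset Dy,Nd --sigma 0.005 --seed 7 -o fp.csv
paragest build-dict --sizes 1,2 --grid 0.5,1,2 -o dict.h5
paragest match --fingerprint fp.csv --dict dict.h5 -o result.json
```

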