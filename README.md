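# bonerad

Primary X-ray radiation damage in bone and other mineralized tissues:
Monte-Carlo photoelectron transport, a convolution damage-spread model,
SHG-image damage quantification, and (002) Debye-ring residual-strain
analysis, with seeded synthetic-data generators for every stage.

## The problem

Hard X-ray microbeams (8–80 keV) are routinely used to image, probe and
sterilize bone. Bone is a nanocomposite of collagen fibrils and
carbonated-apatite (cAP) nanocrystals; the heavy elements of the mineral
(Ca, P) absorb most of the incident photons and re-emit the energy as
photoelectrons and fluorescence. A Ca K-shell ionization by an 18 keV
photon ejects a 13.9619 keV electron that scatters micrometres through
the surrounding matrix, fragmenting the collagen backbone well outside
the directly illuminated volume. Two observable consequences drive the
analysis implemented here:

* **Collagen burn-off**, visible as dark oval imprints in second-harmonic
  generation (SHG) microscopy, whose lateral extent grows with exposure;
* **Residual-strain relaxation** in the pre-stressed cAP nanocrystals:
  dehydration-tensed collagen compresses the mineral along its c-axis, and
  as the collagen fragments the (002) d-spacing relaxes back, measurable
  as a Δc/c shift of the Debye ring.

This package is aimed at beamline users and bone researchers who need to
predict, measure, or emulate these effects.

## The model

The photoelectron source inside a beam of width *w* is a 1-D top-hat,
B(w, x) = rect(x/w). The Monte-Carlo stage produces the penetration-depth
distribution P(d_e) — the probability that an electron's reach along a
line from its origin is d_e, symmetric by construction,
P(+|d_e|) = P(−|d_e|). The energy-deposition profile is the normalized
convolution

    η(w, x) = (B ∗ P)(x) / ∫P(ξ)dξ ,     ∫η dx = w  (energy conservation),

cumulative deposition after exposure Δt is H(w, x, Δt) = Δt·η(w, x), and
the damage half-extent x_w solves H(w, x_w, Δt) = 0.05, a dimensionless
threshold beyond which damage is observed. The relative damage ratio and
damaged volume are

    ζ(w, Δt) = 2|x_w|/w ,      Z(w, Δt) = ζ_H · ζ_V  (ζ_V ≈ 1 in
    strongly fiber-aligned bone, so Z ≈ ζ_H).

Because P is beam-independent while B shrinks with *w*, the relative
damaged volume *grows* as the beam gets smaller — the central, somewhat
counter-intuitive prediction this package reproduces. Damage-vs-time and
strain-vs-time series follow first-order kinetics toward a plateau,
D(t) = D∞ − (D∞ − 100)·e^(−kt), fitted with anchored saturating
exponentials.

## Worked example

```python
from bonerad import (BONE, DamageSpreadModel, ExponentialDamageModel,
                     penetration_depths, penetration_distribution,
                     photoelectron_energy)

energy = photoelectron_energy(18.0, "Ca", "K")   # 13.9619 keV
depths = penetration_depths(energy, BONE, n=10000, seed=1)
pdist = penetration_distribution(depths, material="bone",
                                 energy_kev=energy, seed=1)
model = DamageSpreadModel(pdist)
print(model.sweep([5.0, 10.0, 20.0, 100.0], [320.0]))
```

prints (seed 1):

```
 w_um  dt_s  x_w_um  zeta_h  Z_percent
  5.0 320.0    6.68    2.67     267.05
 10.0 320.0    9.18    1.84     183.52
 20.0 320.0   14.18    1.42     141.76
100.0 320.0   54.18    1.08     108.35
```

Read: after 320 s, a 100 µm beam damages a region only ~8 % wider than
itself, while a 5 µm beam damages ~2.7× its own cross-section — the
damage zone is set by how far photoelectrons scatter (a few µm in bone),
not by the beam size. Fitting first-order kinetics to a noisy synthetic
damage series recovers the programmed rate:

```python
from bonerad.synthetic import gen_damage_curve
t, d = gen_damage_curve(k=0.07, plateau=150.0, noise_sd=3.0, n_points=20, seed=2)
print(ExponentialDamageModel(t, d).fit().summary())
```

```
First-order damage accumulation  D(t) = D_inf - (D_inf - 100) exp(-k t)
  n obs           : 20
  k   (% / s)     : 0.060822  (se 0.007273)
  D_inf (%)       : 150.11  (se 0.6783)
  red. chi-square : 7.258
```

The `bonerad` CLI exposes the same stages (`simulate-electrons`,
`damage-model`, `quantify-shg`, `strain-xrd`, `synthesize`, `full-run`);
`bonerad full-run --seed 0 --out out/` executes the whole chain and
writes a machine-readable summary with seeds and provenance.

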