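# patchstoich

Single-molecule stoichiometry and spatial clustering of membrane-receptor
assemblies from fluorescence microscopy.

Membrane receptors such as chemokine receptors assemble into small puncta on
the cell surface. Two questions about those assemblies drive this package:
**how many molecules does each assembly contain**, and **how are the
assemblies arranged in space**? `patchstoich` answers both for the two data
types the underlying experiments produce:

* **Single-molecule image sequences** (TIRF/HILO-type illumination, one
  GFP per receptor): diffraction-limited foci are detected per frame with
  sub-pixel Gaussian-mask localization, linked into tracks by overlap and
  intensity-ratio gates, and converted to molecule counts. The initial track
  intensity *I*₀ (OLS extrapolation of the first five frames back to the
  start of laser exposure) divided by the single-fluorophore brightness
  *I*₁ gives the stoichiometry *S* = *I*₀/*I*₁. *I*₁ is calibrated from the
  modal brightness of foci after sufficient photobleaching and
  cross-checked against the modal size of single photobleaching steps
  resolved with a Chung–Kennedy edge-preserving filter. The modal
  nearest-neighbour interval of the sorted stoichiometries (Gaussian KDE,
  kernel 0.6 molecules) reveals the oligomer **periodicity** — a value of
  ~2 means the assemblies are built from dimers.
* **Super-resolved puncta images** (SIM reconstructions): puncta are
  segmented by combined global+local Otsu thresholding, reduced to
  centroids, and their spatial arrangement quantified with **Ripley's
  K/L/H** statistics, H(r) = L(r) − r with L(r) = √(K(r)/π): H = 0 under
  complete spatial randomness, H > 0 for clustering, H < 0 for dispersion.
  Scalar summaries are the modal clustering gradient dH/dr and the
  nearest-neighbour distance from the initial negative excursion of H.
  Conditions are compared with the Brunner–Munzel rank test at a
  Bonferroni-adjusted level (0.05/5 = 0.01).

Every stage is validated against a ground-truth **synthetic data generator**
(`patchstoich.synthetic`) that emulates the imaging physics: pixel-integrated
Gaussian PSFs, per-fluorophore geometric photobleaching, Poisson + read
noise, and CSR / jittered-lattice / Thomas-cluster point patterns. See
`docs/methods.md` for the models and all parameter choices.

## Worked example

`examples/02_stoichiometry_and_periodicity.py` simulates three cells of
dimeric (2k-mer) assemblies and runs the full single-molecule branch:

```text
tracks with stoichiometry : 148
mean stoichiometry        : 20.2 molecules
cell 0: I_1 (modal post-bleach) = 102.3 counts, I_1 (bleach steps) = 101.3 counts
cell 1: I_1 (modal post-bleach) = 101.3 counts, I_1 (bleach steps) = 99.6 counts
cell 2: I_1 (modal post-bleach) = 101.4 counts, I_1 (bleach steps) = 100.9 counts
periodicity               : 2.10 +/- 0.20 molecules (6 intervals under the peak)
```

The generator's unitary brightness is 100 counts and the simulated mean
stoichiometry of the draw is ~20 molecules: both calibrations land within a
few percent, and the periodicity of ~2 recovers the dimeric building block.
The other examples cover detection/tracking (`01`), Ripley clustering of
CSR, clustered and lattice patterns (`03`), and between-condition
Brunner–Munzel comparisons (`04`); each prints what it computes and what
the numbers mean.

A thin CLI mirrors the pipeline stages for shell use:

```bash
patchstoich simulate --seed 1 --out run/
patchstoich stoich run/simulated_stack.ome.tif --out run/
patchstoich cluster sim_image.ome.tif --pixel-size-nm 40 --out run/
```

All parameters live in a single YAML-serializable `RunConfig`; every output
table carries the configuration hash that produced it, and identical
configuration + seed reproduce outputs byte for byte.

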