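# oligospot

Single-molecule quantification for live-cell fluorescence microscopy of
bacterial division proteins: fluorophore counting in diffraction-limited
spots, oligomeric-state inference from stoichiometry periodicity,
photobleaching controls and copy-number extrapolation, and membrane-diffusion
analysis from single-particle tracks.

## Who this is for

Groups that tag a protein of interest (e.g. the *E. coli* division protein
FtsK) with a fluorescent protein such as YPet, image live cells on an sCMOS
widefield microscope, and want to answer: *how many molecules are in that
spot, what oligomer are they built from, how many copies does the cell hold,
and how mobile are they?*  The raw data in such experiments are rarely
archivable movies, so the package ships a forward simulator of the whole
acquisition — rod-shaped cells, membrane-bound emitters, midcell oligomer
clusters, per-fluorophore bleaching, Gaussian PSF rendering and camera
noise — and every estimator is validated against that simulator's exact
ground truth.

## The methods

**Counting.** A diffraction-limited midcell spot is fitted with an elliptical
Gaussian `A·G(x; x₀, σ_major, σ_minor, θ) + b` over a small window; its
integrated intensity `I = A·2π·σ_major·σ_minor` (background excluded) is
divided by the single-fluorophore unit intensity `I₁`, calibrated from
reference cells expressing 1–10 monomeric fluorophores whose traces vanish in
a single photobleaching step.  Stoichiometry `S = I / I₁`.

**Periodicity.** If spots are built from a q-mer unit, the values `S` cluster
at multiples of q.  A Gaussian-kernel density of the stoichiometries is
Fourier-transformed; the squared modulus, reindexed from frequency to
periodicity `1/f` (molecules), shows a dominant peak at q.  Quadratic
interpolation refines the peak; its half-width at half maximum measures
sharpness.  Hexamers give a peak at ~6 molecules.

**Bleaching.** Fluorophore survival follows `S(t) = exp(−k·t)` (fitted in log
space with binomial weights).  Partial bleaching thins each spot binomially:
after 50% bleaching a hexamer shows `Binomial(6, ½)` visible copies (mean 3).
Copy numbers observed after bleaching extrapolate to time zero as
`N₀ = N_obs / S(t)`.

**Diffusion.** Spots detected per frame are linked by greedy nearest-neighbour
assignment; the ensemble mean-square displacement over all ordered pairs obeys
`MSD(τ) = 4Dτ + 4σ_loc²` for free 2-D Brownian motion, so `D` is the slope of
the first four lag points divided by 4, with the free intercept absorbing
localization error.  Confined (divisome-tethered) molecules show an MSD that
flattens to a plateau and an apparent `D` indistinguishable from zero.

## Worked example

```bash
python examples/membrane_diffusion.py
```

```
mobile:    D = 0.0393 µm²/s (truth 0.039, intercept 1.64e-3 µm²)
immobile:  D = 3.21e-04 µm²/s, near_immobile = True
confined:  MSD plateaus at 0.0183 µm² (free motion would reach 0.047 µm²)
```

Thirty simulated membrane tracks at 0.039 µm²/s are recovered to 1%; static
emitters observed with 20 nm localization noise read below the 10⁻³ µm²/s
immobility threshold, and disc-confined motion plateaus far below the free
Brownian line — the three signatures used to distinguish freely diffusing
monomers from divisome-anchored complexes.

```bash
python examples/full_pipeline.py
```

```
unit intensity: 204.3 ± 2.3 counts (44 validated single fluorophores)
midcell spots:  50
periodicity:    6.05 molecules (HWHM 0.39)
noncentral  D = 0.0393 µm²/s (near_immobile=False)
midcell     D = -0.0004 µm²/s (near_immobile=True)
```

Here the full image route runs: cells are rendered, the unit intensity is
calibrated from simulated single-fluorophore spots validated by single-step
disappearance, midcell spots are fitted and converted to molecule counts, and
the power spectrum identifies the hexameric building block (true unit
intensity is 200 counts; true periodicity 6).

The other examples (`hexamer_periodicity.py`, `count_midcell_spots.py`,
`bleach_extrapolation.py`) each demonstrate one capability in ~30 lines.

A thin CLI wraps the same pipelines:

```bash
oligospot periodicity --input spots.csv --bandwidth 0.7 --range 2:20
oligospot pipeline --config cfg.yaml --out run/
```

## Layout

```
src/oligospot/      synthetic.py   ground-truth simulator (cells, emitters,
                                   bleaching, PSF/camera rendering, tracks)
                    quantify.py    background, Gaussian fitting, calibration,
                                   whole-cell intensities
                    periodicity.py KDE, power spectrum, peak finding
                    bleaching.py   decay fits, binomial thinning, extrapolation
                    diffusion.py   detection, linking, MSD, D estimation
                    pipeline.py    end-to-end orchestration + manifests
                    io.py, cli.py  TIFF/CSV/JSON formats, command line
examples/           one narrative script per capability
docs/methods.md     models, parameter choices, limitations
tests/              unit, property and acceptance suites
```
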