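# olfactomap

Current source density (CSD) mapping of odor-evoked activity on insect
antennae from multi-position electroantennogram (EAG) recordings — with
companion tools for sensilla morphometrics and between-species comparison.

## Who this is for

EAGs are the workhorse of insect chemical ecology, but a single-position
EAG is biased toward the receptor neurons nearest the electrode. Recording
at several positions along the funiculus (the third antennal segment) and
inverting a simple volume-conductor model localizes *where* on the antenna
each odorant evokes activity. `olfactomap` implements that inversion, the
signal processing around it, kernel density maps of sensilla annotated
from SEM micrographs, and the statistics used to compare antennal maps
between species. A fully seeded synthetic-data generator makes every stage
testable without any recordings.

## The model

A point current source I_c in a medium of conductivity σ creates the
potential φ = I_c/(4πσr) at distance r. The funiculus surface is unfolded
into a plane; current sources are piecewise-constant over N rectangular
compartments (one per electrode at positions 0, 1/3, 2/3, 1 of the
proximo-distal axis), each spanning the unfolded circumference
(half-extent q, from Ramanujan's ellipse-perimeter approximation
π(3(a+b) − √((3a+b)(a+3b)))). The potential at electrode x_j per unit
source density in compartment i is

    F_ij = 1/(4πσ) ∫_{−q}^{q} ∫_{x_i − h/2}^{x_i + h/2} dx dy / √((x − x_j)² + y²)

(end compartments are half-width: no receptor neurons lie beyond the
first and last electrodes). The integral has a closed form that stays
finite at the electrode singularity. With φ = F·C square (N = 4), the CSD
is C = F⁻¹·φ at every time sample. Each compartment's source is integrated
over 1.5 s after stimulus onset (sign-flipped so activation is positive)
and summarized by the **spatial barycenter** — the activation-weighted mean
electrode position on [0, 1].

Between-species comparisons use the **distance ratio** (mean Euclidean
distance of feature vectors between species over the mean within species)
tested against 1 by bootstrap, plus LDA and PCA projections. Sensilla maps
use 2D Gaussian kernel density (σ = 2% of length, 5% of width) and the
**dominance index** (D_b + D_c − D_t)/(D_b + D_c + D_t) contrasting
food-odor (basiconic + clavate) against trichoid sensilla.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from olfactomap import CurrentSourceDensity, preprocess
from olfactomap.simulate import SimulationConfig, simulate_recording

cfg = SimulationConfig()                       # synthetic defaults, SNR 20
est = CurrentSourceDensity(cfg.geometry).fit()
rec, truth = simulate_recording(cfg, center_norm=0.6,
                                rng=np.random.default_rng(0),
                                odorant="hexenyl_acetate")
res = est.analyze(preprocess(rec))
print(f"condition number : {est.condition_number_:.2f}")
print(f"response areas   : {np.round(res.response_areas, 3)}")
print(f"barycenter (est) : {res.barycenter_norm:.3f}")
print(f"barycenter (true): {truth['barycenter_norm']:.3f}")
```

prints

```
condition number : 6.55
response areas   : [ 0.291  4.963 49.774 -0.217]
barycenter (est) : 0.633
barycenter (true): 0.632
```

A simulated source centred at 0.6 of the proximo-distal axis activates
mostly the compartment at electrode 2/3 (area 49.8, in source units × s;
the small negative area at the tip is noise), and the recovered barycenter
matches the ground truth to ~0.001 at an EAG signal-to-noise ratio of 20.

The same pipeline from the shell:

```sh
olfactomap simulate --out demo --seed 7 --n-individuals 3
olfactomap csd --recording demo/ind00_linalool.tsv --geometry demo/geometry.yaml --out demo/csd
olfactomap sensilla-summary --sensilla sensilla.csv --out demo/counts
olfactomap compare --features features.tsv --n-boot 10000 --seed 1 --out demo/cmp
```

Every run writes a `manifest.json` with input hashes, parameters and the
seed. Exit codes: 0 success, 2 validation error, 3 numerical failure.

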