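# ligandconf

Free-ligand conformational dynamics from solution NMR, as a tested Python
pipeline.

In small-molecule drug discovery the solution ensemble of the *free* ligand
matters: if half of the compound is locked in a non-bioactive rotamer, that
population is paid for at binding time. `ligandconf` implements the
quantitative toolchain an NMR conformational-analysis platform uses to
characterize such systems:

- **Two-site exchange lineshapes** (`ligandconf.lineshape`) — absorption
  spectra of a spin exchanging between two sites from slow exchange through
  coalescence (`k_c = πΔν/√2`) to fast exchange, with linewidth
  (`Δν½ = R₂/π`) and peak-count measurements.
- **EXSY kinetics** (`ligandconf.exsy`) — selective-EXSY build-up curves
  `f(τ) = ½(1 − e^(−2kτ))` fitted for first-order exchange rates, half-lives
  `t½ = ln 2/k`, Arrhenius regression of `ln k` vs `1/RT` (slope `−Ea`), and
  Eyring conversion `ΔG‡ = RT·ln(k_B T/(h k))`.
- **Replica-exchange torsional sampling** (`ligandconf.rex`) — a
  parallel-tempering Metropolis sampler on analytic torsion potentials,
  standing in for solute-tempering MD, with histogram, free-energy-profile,
  radial (spiral) and ergodicity reports. This reproduces the key
  phenomenology: a 20 kcal/mol double well sampled by a single 300 K walker
  never leaves its starting well, while a hot replica ladder equilibrates to
  the 50/50 populations the NMR spectrum shows.
- **Conformer tools** (`ligandconf.conformers`) — periodic torsion metrics,
  Kabsch RMSD with mirror handling, complete-linkage clustering to diverse
  representatives, Boltzmann populations, and ensemble averaging of NMR
  observables (linear for shifts/couplings, `⟨r⁻⁶⟩^(−1/6)` for NOE
  distances).
- **Population fitting** (`ligandconf.popfit`) — NAMFIS-style
  simplex-constrained least squares of conformer weights against observed
  shifts, couplings and distances, with pruning and multi-start
  determinism.
- **Shift-list parsing** (`ligandconf.shiftlist`) — printed ¹H shift lists
  (ACD dialect) parsed to structured entries with exact rational integrals,
  plus rotamer population accounting from resolved isomer-tagged signal
  pairs.
- **Synthetic data** (`ligandconf.synthetic`) — seeded generators for every
  input the pipeline needs (EXSY datasets with Arrhenius-consistent ground
  truth, VT lineshape stacks, calibrated torsion potentials, conformer
  ensembles with known weights), each carrying a provenance block.

## Worked example

Fit a variable-temperature EXSY dataset and read off the rotational barrier:

```python
import numpy as np
from ligandconf import exsy, synthetic as syn

truth = syn.ArrheniusTruth.from_rate(Ea=19.9, k_ref=np.log(2) / 0.5, t_ref=300.0)
data = syn.gen_exsy_dataset(truth)          # 300/305/310 K, 8 mixing times
fits = exsy.fit_dataset(data)
arr = exsy.fit_arrhenius(fits)              # warns: only a 10 K span

print(f"k(300 K)  = {fits[0].k:.3f} /s")
print(f"t1/2      = {fits[0].t_half:.3f} s")
print(f"Ea        = {arr.Ea:.1f} kcal/mol")
print(f"dG‡(300K) = {exsy.eyring_barrier(fits[0].k, 300.0):.1f} kcal/mol")
```

prints

```
k(300 K)  = 1.386 /s
t1/2      = 0.500 s
Ea        = 19.9 kcal/mol
dG‡(300K) = 17.4 kcal/mol
```

i.e. a rotamer pair interconverting with a half-second half-life at room
temperature sits ~17 kcal/mol above the well — firmly in slow exchange
(`exsy.classify_exchange_regime(1.386, 100.0)` → `"slow"`), consistent with
the doubled peaks and 1:1 integrals the parser extracts from the packaged
dimethyl-compound shift list:

```python
from ligandconf import shiftlist as sl
ra = sl.rotamer_fractions(sl.load_compound(2))
print({k: float(v) for k, v in ra.fractions.items()})
# {'isomer1': 0.5, 'isomer2': 0.5}
```

A command-line interface mirrors the library
(`ligandconf simulate | exsy-fit | lineshape | rex-run | rex-report |
cluster | popfit | parse-shifts | run`); `ligandconf run --config cfg.yaml`
executes the whole pipeline and writes a checksummed manifest.

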