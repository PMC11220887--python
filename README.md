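# sadret

SAD heavy-atom substructure determination by a modified dual-space
phase-retrieval algorithm: a relaxed averaged alternating reflections
(RAAR) iteration augmented with π/2 phase perturbation of weak reflections
and tangent-formula refinement of strong reflections, plus everything
around it — Bijvoet-pair preparation (anomalous differences, resolution
cutoff, E normalization), space-group symmetry handling, peak search,
symmetry/origin/enantiomorph-aware site matching, and a synthetic SAD data
simulator so the whole pipeline is testable without external data.

## Library quick start

```python
import sadret as sr

cell = sr.UnitCell(38, 44, 52)
sg = sr.SpaceGroupOps.from_symbol("P212121")   # or from_strings(["x,y,z", ...])

# synthetic Bijvoet data with ground truth
spec = sr.SyntheticSpec(cell=cell, sg=sg, n_atoms=6, n_background=300,
                        d_min=2.2, noise_frac=0.02, seed=11)
pairs, truth = sr.make_dataset(spec, "bijvoet")

# |dF| extraction, |dF|/sigma = 1.2 resolution cutoff, E normalization
refl, shells, d_cut = sr.prep_pipeline(pairs, cell, sg)

# multi-trial phase retrieval (beta=0.82, 13% low-density perturbation,
# weak fraction auto over 20-50%, tangent-refined strong set)
cfg = sr.EngineConfig(n_iter=500, n_trials=50, algorithm="raar_pihalf_tf", seed=4)
best, summary = sr.run_multi(refl, cell, sg, cfg)

# peak search and comparison against the reference substructure
peaks = sr.find_peaks(best.final_density, sr.default_n_peaks(6), cell=cell, sg=sg)
report = sr.match_sites(peaks, truth["sites"], sg, cell, tol=1.5)
print(report.fraction_matched, report.rmsd_dist, report.success)
```

Algorithm variants for comparison runs: `cf` (charge flipping), `raar`
(plain), `raar_pihalf`, `raar_pihalf_tf` (default, the full modified
algorithm).

## CLI

```bash
sadret simulate --cell "38 44 52" --symops P212121 --mode bijvoet \
    --n-atoms 6 --n-background 300 --d-min 2.2 --noise-frac 0.02 \
    --seed 11 --out sim/
sadret prep  --pairs sim/pairs.hkl --cell "38 44 52" --symops P212121 --out prepped.hkl
sadret solve --hkl prepped.hkl --cell "38 44 52" --symops P212121 \
    --trials 400 --iters 750 --algorithm raar_pihalf_tf --seed 7 --out solved/
sadret peaks --map solved/best.map --n 8 --symops P212121 --out sites.csv
sadret match --calc sites.csv --ref sim/truth_sites.csv \
    --cell "38 44 52" --symops P212121 --tol 1.5
sadret run   --config config.yaml --out run/      # composite pipeline
```

Space groups are given either as one of the built-in symbols or as an
explicit `;`-separated operator list (`"x,y,z;-x,y+1/2,-z"`). Every output
directory contains a `manifest.json` (config echo, input digests, seeds,
timings) sufficient to reproduce the run.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks
(site recovery on noise-free and noisy synthetic problems, algorithm
variant ordering, oracle comparisons, invariants). The full suite takes
roughly 20 minutes on one CPU; everything else finishes in under a minute.

## Layout

- `src/sadret/symmetry.py` — unit cell, space-group operators, reflection
  expansion/reduction, systematic absences, permissible origin shifts
- `src/sadret/prep.py` — Bijvoet differences, resolution cutoff, E values
- `src/sadret/engine.py` — the dual-space retrieval engine and its
  elementary operations (projection, π/2 perturbation, tangent refinement,
  RAAR/CF real-space updates, CC/figures of merit)
- `src/sadret/sites.py` — peak search and site-list matching
- `src/sadret/simulate.py` — synthetic SAD data with ground truth
- `src/sadret/hklio.py` — HKL/CSV/PDB/CCP4 readers and writers
- `src/sadret/cli.py` — the `sadret` command
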