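# clashfix

Semiempirical and force-field energy models that lack a long-range van der
Waals (vdW) repulsion term produce protein geometries full of *clashes* —
non-bonded, non-hydrogen-bonded atom pairs squeezed at least 0.4 A inside
the sum of their vdW radii. `clashfix` implements the machinery for
diagnosing and curing that pathology:

* the **piecewise-Gaussian repulsion pair term**
  `E(r) = a·exp(−b(c−r)²)` for `r > c`, plateauing at `a` for `r ≤ c`,
  with analytic forces, summed over non-bonded pairs of a structure;
* **proxy reference data** — rigid small-molecule dimers placed once at
  the vdW contact distance and once far apart, whose energy difference
  isolates a single diatomic repulsion — with the class-based weighting
  scheme (heats of formation ~1, hydrogen bonds ~10, clash proxies
  30-100 per (kcal/mol)⁻¹);
* **weighted least-squares fitting** of the (a, b, c) parameters for all
  element pairs simultaneously, including the **clash-driven reweighting
  loop**: fit, optimize test structures, detect clashes, raise the weights
  of the offending pairs' proxy data, repeat until the average clashscore
  is acceptably small;
* the **validation protocol** used to judge the outcome: Molprobity-style
  clash detection and the per-1000-atom clashscore, Kabsch backbone RMSD,
  solvent-accessible-surface volumes, O-H···O hydrogen-bond surveys,
  bond/angle outlier scans, and the survey statistics (means,
  count-weighted means, excess kurtosis) that aggregate per-protein and
  per-benchmark tables;
* a documented **surrogate energy model** (harmonic frame + attraction
  wells + soft core, deliberately missing long-range repulsion) and
  **synthetic-structure generators** (proxy dimers, extended poly-alanine
  toy chains with exactly planted clashes, interaction-energy survey
  sets), so the entire protocol runs end to end on synthetic data in
  minutes.

It is aimed at method developers who want a desk-scale, fully inspectable
reproduction of how a weak repulsive correction is parameterized and
validated, and at anyone needing the individual pieces (clashscore,
backbone RMSD, proxy-dimer construction) as a library.

## Worked example

Survey aggregation over the shipped 21-protein validation tables
(per-protein clashscores, backbone RMSDs and volume changes for
structures optimized with PM6-ORG, PM6-D3H4 and PM7, plus the
interaction-energy benchmark summary):

```text
$ clashfix survey
quantity	PM6-ORG	PM6-D3H4	PM7
clashscore_mean	4.72	32.41	28.76
backbone_rmsd_mean	0.96	0.83	0.97
volume_pct_change_mean	-5.80	-5.13	-7.60
interaction_aue_weighted	1.72	1.82	2.58
```

Reading: geometries optimized with the repulsion-corrected method
(PM6-ORG) average 4.72 clashes per 1000 atoms versus ~30 for its
uncorrected predecessors — a ~7x improvement — while backbone RMSD
(Angstroms) and compaction (% volume change vs experiment) stay in the
same range, i.e. the clashes were not fixed by trivially inflating the
structures. The last row is the count-weighted average unsigned error
(kcal/mol) over 688 benchmark interaction energies.

The same machinery, programmatically, on a synthetic fixture:

```python
>>> from clashfix.synthdata import make_toy_chain
>>> from clashfix.validate import detect_clashes
>>> chain, graph, ledger = make_toy_chain(20, planted_clashes=3, overlaps=(0.5, 0.5, 0.5))
>>> report = detect_clashes(chain, graph)
>>> len(report.clashes), round(report.clashscore, 2)
(3, 15.08)
>>> sorted((i, j) for i, j, _ in ledger) == sorted((c.i, c.j) for c in report.clashes)
True
```

A 20-residue chain has 199 atoms, so the three planted 0.5 A overlaps
give a clashscore of 1000·3/199 = 15.08, and the detector finds exactly
the planted pairs.

The full clash-cure protocol — optimize toy chains under the
repulsion-free surrogate (heavy clashing), then fit the pair term with
the reweighting loop and re-optimize — is run by
`clashfix reweight-loop --out params.txt --trace trace.tsv` or, with all
intermediate numbers, by the acceptance script below.

## Layout

| module | contents |
| --- | --- |
| `clashfix.structures` | PDB I/O (via gemmi), topology inference + ADD/DEL edits, neighbor pairs |
| `clashfix.repulsion` | the pair term, parameter sets, structure sums, parameter files |
| `clashfix.surrogate` | surrogate energy model, L-BFGS optimizer, interaction energies |
| `clashfix.refdata` | rigid molecule library, proxy construction, weights, AUE |
| `clashfix.paramfit` | `RepulsionFit`/`RepulsionFitResults`, the reweighting loop |
| `clashfix.validate` | clashes, RMSD, volumes, H-bond survey, outliers, survey stats, shipped tables |
| `clashfix.synthdata` | toy chains, dimers, survey sets, training sets, study conditions |
| `clashfix.cli` | `clashfix` command-line interface |

See `docs/methods.md` for the model descriptions, parameter choices and
limitations.
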