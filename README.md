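# badgerqc

Identity quality control for studies that profile the same people on two
array platforms — expression arrays and genotyping arrays. In any large
retrospective study some samples end up on the wrong array (plate swaps,
pipetting slips, rotated plates, mislabelled tubes), and a mismatched
pair silently corrupts every downstream analysis. `badgerqc` detects
these mix-ups, diagnoses *which* plating error produced them, and
corrects the sample map, using cis-eQTLs as a many-locus genetic
fingerprint readable from expression data alone. It is aimed at analysts
running multi-platform (cancer) cohorts and at lab teams designing plate
layouts that make such errors detectable in the first place.

## The statistic at the core

For each eQTL pair *i* (expression probe + SNP), kernel-density estimates
f_AA, f_AB, f_BB of the per-genotype expression distributions are fitted
on trusted matched arrays. From the intensity e_ij of probe *i* on
expression array *j*, the posterior genotype under equal priors is
P(g | e) = f_g(e) / Σ f_g'(e), and the predicted B-allele count is the
posterior mean p_ij ∈ [0, 2]. Against the observed counts o_ik of
genotype array *k*:

    B_jk = (I / I_jk) · Σ_i (p_ij − o_ik)²     (sum over jointly observed eQTLs)

Low score = likely the same individual. Per expression array, scores are
ranked (rank matrix **BR**; intended partners should be rank 1) and the
gap Δ = B_(g+1) − B_(1) past any g replicate arrays measures confidence.
Under-performing eQTLs are pruned by their discrepancy
d_i = mean squared residual over well-matched pairs, and the whole
procedure iterates — rescore, propose corrections (cycles and chains on a
bipartite mismatch graph, plus systematic plate-transform searches over
the recorded plate provenance), apply the confident ones, refit — until a
confirming pass changes nothing.

The package also contains the plate-design side of the problem
(sex-pattern layouts that expose wrong-plate and wrong-orientation
errors; an 8×12 plate has 172 neighbour pairs, of which a good design
leaves few same-sex), array-quality metrics that predict matching power
(P95 and a perfect-vs-intergenic rank-separation score), and a synthetic
cohort generator with planted errors, population structure, relatives and
tumour distortion so the whole pipeline is testable without any external
data.

## Worked example

Simulate a 96-sample cohort with one planted neighbour swap on the
genotyping plate, then let the iterative loop find and fix it:

```python
from badgerqc import simulate, engine
from badgerqc.simulate import SimulationConfig, NeighbourSwap

cohort = simulate.simulate_cohort(
    SimulationConfig(seed=42, error_spec=(NeighbourSwap("genotype"),))
)
result = engine.run_badger(cohort.expr, cohort.geno, cohort.smap)
for it in result.iterations:
    print(f"iteration {it.index}: {it.n_eqtls} eQTLs, "
          f"{it.n_unresolved} unresolved, {it.n_accepted} accepted")
for corr in result.report.corrections:
    if corr.moves:
        moves = ", ".join(f"{m.sample_id}->{m.genotype_array}" for m in corr.moves)
        print(f"{corr.kind} ({corr.platform}): {moves}")
print("restored:", result.final_map.assignment_signature()
      == cohort.truth_map.assignment_signature())
```

prints

```
iteration 1: 50 eQTLs, 2 unresolved, 1 accepted
iteration 2: 50 eQTLs, 0 unresolved, 0 accepted
swap (genotype): S092->G093, S093->G092
restored: True
```

Reading it: the internal cis scan recovered all 50 simulated eQTLs;
exactly two arrays failed the rank-1 check; the evidence formed a
two-cycle, attributed to the genotyping platform, and swapping S092/S093
back restored the true map, after which a confirming iteration found
nothing left to do. The same run from the shell:

```sh
badgerqc simulate --seed 42 --out-dir cohort   # writes expr.tsv, geno.tsv, map.csv, layouts/
badgerqc run --in-dir cohort --out-dir fixed   # corrected_map.csv, report.json, iterations.json
```

For plate design:

```sh
badgerqc design-plate --kind blocked_12221
# {"kind": "blocked_12221", "same_sex_pairs": 36}
badgerqc layout-stats --n-plates 100 --reps 200 --seed 7
```

the first reports that the blocked 1-2-2-2-1 design leaves 36 of the 172
neighbour pairs undetectable by a sex check (3 per column), the second
that a random balanced layout leaves about 85 and that the closest two of
100 random plates differ in about 30 wells — i.e. at least 15 simple
switches, so random layouts are mutually distinguishable.

## Layout

- `src/badgerqc/core.py` — domain containers (matrices, sample map with
  plate provenance, scores/ranks, plate layouts, corrections).
- `src/badgerqc/simulate.py` — synthetic cohorts with planted errors.
- `src/badgerqc/eqtl.py` — cis association scan and per-genotype KDE.
- `src/badgerqc/engine.py` — prediction, scoring, ranking, gap statistic,
  refinement, the iteration loop.
- `src/badgerqc/resolve.py` — mismatch graph, cycles/chains/slippage,
  plate transforms, platform attribution.
- `src/badgerqc/plates.py` — sex-pattern designs and layout simulations.
- `src/badgerqc/quality.py` — array-quality metrics.
- `src/badgerqc/io.py`, `src/badgerqc/cli.py` — file formats and the
  command line.

See `docs/methods.md` for the model, parameter defaults and limitations.
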