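# mosaicscan

Comparative-genomics analysis of **phage genome mosaicism**: detect
recently exchanged segments (*mosaics*) between phage and prophage
genomes, test whether homologous recombination left *traces* in the
sequences flanking each exchange, and summarize the result by phage
lifestyle (temperate / defective / virulent).

Intended for phage and mobile-element genomicists who want a
self-contained, scriptable reimplementation of this screen — no
external aligner binaries, fully deterministic, and testable end to end
on synthetic cohorts with planted ground truth.

## The screen

For a genome pair with background identity *b*:

- **mosaic** — a local alignment ≥ 100 bp with identity > 90%: a
  segment exchanged recently enough that it has not diverged.
- **HR trace** — after global re-alignment of the 2-kb flanks of a
  mosaic, a 50-bp window with identity ≥ *b* + 10 points, where *b* is
  the flank's median window identity.  Recombination across
  pre-existing homology predicts such a patch at the boundary; a
  cut-and-paste (illegitimate) exchange does not.
- **null model** — with gap-free background, window matches are
  Binomial(50, *b*); the chance a window reaches *b* + δ is
  q = P[Bin(50, b) ≥ ⌈50(b+δ)⌉] and
  P(≥1 trace) = 1 − (1 − q)^(windows × sides).
- Pairs too related for the signal to mean anything are removed first
  by fragment ANI (adapted Goris method with permissive scoring:
  +3/−4, gap 5/2, word 10): redundant above 92% ANI / 80% coverage,
  excluded above 70%/50% (temperate/defective) or 68%/48% (virulent).

A synthetic-cohort generator plants mosaics, flanking homology
anchors, trace-masking events and IS repeats with exact truth tables,
so every stage is validated without downloading genomes.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort (10 pairs of 45-kb genomes at 60% background
identity, 3 planted exchanges per pair):

```bash
python analysis/01_simulate_cohort.py --seed 1 --outdir results/cohort
python analysis/02_relatedness_screen.py --cohort results/cohort --out results/ani.tsv
python analysis/03_detect_mosaics.py   --cohort results/cohort --outdir results
python analysis/04_call_traces.py      --cohort results/cohort --outdir results
python analysis/05_summarize.py        --cohort results/cohort --outdir results
```

Output (seed 1):

```
wrote 20 genomes (45000 bp) to results/cohort
planted 30 mosaics over 10 pairs; realized background identity 60.1%

10/10 pairs analyzed (mean ANI 84.1%)

detected 30 mosaics on 10 pairs
median length 456 bp, median identity 96.5%
recall 1.000, precision 1.000 vs planted truth

30 mosaics: 0 with no trace, 0 with one, 30 with two
trace fraction 100.0% (per-side null rate 0.357)
planted-anchor trace recall 1.000 over 60 sides
```

Reading this: every pair survives the relatedness screen (ANI is
computed over the few fragments that align at 60% background, hence
the high mean but near-zero coverage); all 30 planted exchanges are
recovered with no false positives; and because every planted mosaic
carries homology anchors on both sides, trace calling finds two traces
per mosaic — far above the ≈0.36 per-side rate expected by chance in
the boundary-proximal search window.  Raising the masking probability
(`SimConfig(p_mask=...)`) converts two-trace mosaics into one-trace
mosaics, reproducing the signature of successive exchanges.

The same machinery is exposed as a CLI
(`mosaicscan simulate | ani | scan | report`) and as a library:

```python
from mosaicscan import SimConfig, simulate_cohort, detect_mosaics, call_traces
genomes, truth = simulate_cohort(SimConfig(seed=1, n_pairs=2, genome_len=20000))
mosaics = detect_mosaics(genomes[0], genomes[1])
call = call_traces(mosaics[0], genomes[0], genomes[1], proximal_cols=250)
print(len(mosaics), call.n_traces)
```

`docs/methods.md` documents the model, estimator choices, null-model
calibration and the generator's scope.

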