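# mybdna

How does an R2R3-MYB transcription factor read its DNA element — and how do
the DNA methylation marks 5mC and 6mA interfere? `mybdna` packages the three
desk-scale analyses behind that question, built around the Arabidopsis
WER (WEREWOLF) / 5′-AACNDN-3′ system (IUPAC D = A/G/T, N = any base):

1. **Motif/methylome census** — scan genome promoter windows (0–3 kb
   upstream of each TSS) for a degenerate element on both strands, and
   intersect the occurrences with strand-specific single-base 5mC/6mA
   calls: 5mC at motif position 3 (the C of the AAC core), 6mA at
   positions 1 and 2 (the two adenines), tallied into the eight
   combination categories plus marginals.
2. **Structural base-readout analysis** — from atomic coordinates of a
   protein–DNA complex, enumerate direct hydrogen bonds (donor/acceptor
   complementarity within d_hb = 3.5 Å), apolar proximities (≤ 4.5 Å) and
   single-water bridges; classify base-specific versus backbone contacts;
   and apply two sensitivity rules: a **5mC steric screen** (a virtual
   5-methyl carbon placed along the C4→C5 direction at 1.50 Å from C5 must
   not clash with protein atoms) and a **6mA donor-occlusion rule** (an
   adenine whose exocyclic N6 amine donates a base H-bond is flagged —
   N6 methylation compromises that donation).
3. **One-site ITC isotherm** — forward-simulate the single-set-of-sites
   (Wiseman) binding isotherm

   Q = (n·Mt·ΔH·V₀/2)·[1 + Xt/(n·Mt) + 1/(n·Ka·Mt) −
   √((1 + Xt/(n·Mt) + 1/(n·Ka·Mt))² − 4·Xt/(n·Mt))]

   with displaced-volume corrections, fit (n, K_d, ΔH, q₀) by nonlinear
   least squares, and summarize affinity effects as K_d fold-changes and
   the c = n·M₀/K_d design diagnostic.

A fourth module, `mybdna.synthetic`, generates every input with recorded
ground truth (planted-motif genomes, methylomes, idealized interface
fixtures, noisy thermograms) so the whole pipeline is testable without any
external download; `mybdna.pipeline` / the `myb` CLI orchestrate
reproducible runs. See `docs/methods.md` for the models, conventions and
limitations.

## Worked example

```sh
python examples/03_itc_fit.py
```

```
true Kd:     51.0 nM   fitted Kd:   52.8 nM
fitted n:   1.001      fitted dH:  -7993.1 cal/mol
c = 379 (fittable window 1..1000: True), converged: True

fold-changes vs wild type (Kd ratios):
  5mC-modified element:  45.8x
  C10:G mutant:          39.3x
  A12:T mutant:          50.8x
```

A 24 × 1.6 µl titration of 400 µM protein into 20 µM DNA duplex is
simulated at a true K_d of 51 nM with 1% heat noise and refit: the
recovered K_d (52.8 nM) is within 4% of truth, the stoichiometry refines
to ~1 site, and c ≈ 379 sits comfortably inside the fittable window. The
fold-change lines divide variant K_d values by the wild-type K_d: the
5mC-modified element binds ~46-fold more weakly, the two strongest core
mutants ~39- and ~51-fold.

The other examples exercise the census (`01_motif_census.py`: a 100 kb
synthetic genome; 2102 promoter instances of which 150 are planted, census
identical to the naive enumeration oracle), the structural readout
(`02_structure_readout.py`: seven contacts at their requested distances,
one 5mC steric flag on the cytosine, 6mA flags on both adenines) and the
end-to-end pipeline (`04_end_to_end_demo.py`, equivalent to
`myb demo --seed 1 --out-dir demo_out`).

## Command line

```sh
myb scan --genome genome.fa --annotation genes.gff3 --out hits.bed
myb census --genome genome.fa --annotation genes.gff3 \
    --meth-5mc 5mC.bed --meth-6ma 6mA.bed --out-dir run/
myb contacts --pdb complex.pdb --d-hb 3.5 --d-ap 4.5
myb methyl-sense --pdb complex.pdb
myb itc-sim --kd 0.051 --out tg.tsv && myb itc-fit --thermogram tg.tsv
myb simulate genome --seed 7 --out-dir synth/
myb demo --seed 1 --out-dir demo_out/
```

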