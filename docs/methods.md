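# Methods

`mybdna` re-implements, as a tested library, the three desk-scale analyses
behind the question *how does an R2R3-MYB transcription factor read its DNA
element, and how do 5mC/6mA marks interfere?* — using the Arabidopsis WER
(WEREWOLF) / AACNDN system as the concrete model.

## 1. Degenerate-motif scanning and the methylome census

**Model.** The WER binding element is the degenerate hexamer 5′-AACNDN-3′
(IUPAC D = {A, G, T}, N = {A, C, G, T}). Promoters are defined as the 0–L bp
region upstream of a gene's annotated 5′ end (TSS), with L = 3000 bp by
default. A motif instance is any window position whose slice matches the
pattern position-wise; minus-strand instances are found against the reverse
complement and reported in genomic (plus-strand) coordinates. The census
intersects instances with strand-specific single-base methylation calls:
5mC at motif position 3 (the C of the AAC core) and 6mA at positions 1 and
2 (the two adenines), yielding eight combination categories plus marginals.

**Conventions and edge cases.**

* Coordinates are 0-based half-open internally; BED on disk; GFF3's
  1-based closed intervals are converted on read (via pyranges).
* TSS is the annotated *gene* 5′ end, not transcript-level: the finer
  annotation layer adds nothing to a synthetic-genome study and real
  inputs rarely agree on transcript sets.
* Both strands are scanned by default (a `strands` flag restricts to one
  for sensitivity analysis). Genomic N matches no pattern code, including
  pattern N: an unknown base must not create phantom motifs.
* An instance contained in several overlapping promoter windows is counted
  once as a motif and credited to every overlapping gene.
* Methylation calls must match the motif strand (5mC/6mA are per-strand
  chemical marks); duplicate calls are deduplicated by
  (chrom, pos, strand, type); an optional minimum-score filter is off by
  default.

**Implementation and verification.** The scanner is a vectorized
position-wise table lookup (numpy); its reference is a deliberately naive
regex-enumeration oracle kept in `mybdna.synthetic`. Scanner/oracle
equivalence is asserted property-style on random sequences and patterns,
and end-to-end on megabase synthetic genomes. Published genome-wide counts
for Arabidopsis depend on the genome/annotation release and are therefore
not test gates.

## 2. Structure-based base readout and methylation-sensitivity rules

**Contact model.** From atomic coordinates (PDB subset; first altloc kept,
occupancy ignored), contacts are enumerated with distance-only criteria —
crystal models carry no hydrogens, so no donor–acceptor angle term is
applied:

* direct H-bond: protein donor ↔ DNA acceptor (or the reverse) within
  d_hb = 3.5 Å (generous around the 2.7–3.0 Å bonds typical of
  major-groove readout);
* apolar proximity: protein apolar carbon/sulfur ↔ DNA base carbon within
  d_ap = 4.5 Å;
* water bridge: one water O within d_hb of both a protein polar atom and a
  DNA polar atom, one record per (protein atom, water, DNA atom) triple;
  complementarity is not enforced through the water.

Each contact carries a base/phosphate/sugar class; a DNA residue with at
least one base-class contact is *base-specific*, otherwise
*backbone-only*. His ND1/NE2 are donor+acceptor (protonation unresolved);
Cys SG and Met SD are treated as apolar sulfurs rather than H-bond
partners (a conservative screen convention). Residue numbering follows the
input file; the default reading-helix windows are H3 = 54–65 and
H6 = 105–116 and are user-overridable.

**Methylation rules.**

* **5mC steric rule.** For each read-out cytosine, a virtual 5-methyl
  carbon is placed in the base plane along the C4→C5 exocyclic direction
  at 1.50 Å from C5 (planar idealized; no rotamer search — the argument is
  geometric proximity, not energetics). The site is flagged if any protein
  atom falls within vdW_C + vdW_other − 0.4 Å of that virtual carbon
  (vdW radii C 1.70, N 1.55, O 1.52, S/P 1.80 Å), or if a protein apolar
  atom already packs against C5 at ≤ 4.0 Å.
* **6mA donor-occlusion rule.** An adenine is flagged when its N6 amine
  donates at least one direct base H-bond; N6 methylation compromises that
  donation.

**Fixtures.** The synthetic fixture builder assembles idealized planar base
templates (standard reference-frame geometries; bond lengths within 0.1 Å
of standard values, asserted in tests) and single-atom probe residues
placed at exact requested distances along the outward exocyclic bisector
(or a caller-supplied direction, e.g. the in-plane point equidistant from
guanine O6 and N7 for a bidentate lysine read). Base groups are spaced
30 Å apart so they cannot cross-talk, and the builder brute-forces all
pairs and refuses any geometry that realizes a contact beyond the planted
list. The composite interface fixture plants the five printed readout
geometries of the WER-class interface (2.9, 3.0, 2.9-bidentate, 3.7 and
2.7 Å) plus the second adenine's N6 H-bond at 3.0 Å, so that both adenines
of the AAC core donate through N6 and both methylation rules fire.

## 3. One-site ITC isotherm

**Model.** Single-set-of-sites (Wiseman) isotherm, the model standard ITC
software fits. Per injection, cell concentrations follow the symmetric
displaced-volume convention Mt = M0(1−v/2V0)/(1+v/2V0),
Xt = X0(v/V0)/(1+v/2V0); cumulative heat is the quadratic-root
bound-fraction expression Q = (n·Mt·ΔH·V0/2)·[1+r+1/(n·Ka·Mt) −
√((1+r+1/(n·Ka·Mt))²−4r)] with r = Xt/(n·Mt), and the injection heat is
the finite difference with the (dV/V0)·(Qi+Qi−1)/2 correction plus a
per-injection baseline q0. Units: µl, µM, cal/mol, µcal.

**Defaults** mirror the study protocol: 24 × 1.6 µl injections, 400 µM
titrant (protein, syringe) into 20 µM macromolecule (DNA duplex, cell),
25 °C; V0 = 200 µl (iTC200 nominal — configurable, since the instrument,
not the cell volume, is what protocols usually state). The protein-into-DNA
orientation is assumed throughout. An optional `--drop-first` discards the
first-injection mixing artifact (off by default).

**Fitting.** Nonlinear least squares (scipy `least_squares`, trust-region
reflective, positivity bounds on n and Kd) over (n, Kd, ΔH, q0);
initialization n = 1, Kd = M0/10, ΔH = sign(largest |heat|)·5000, q0 =
mean of the last three heats. Standard errors come from the Jacobian at
the solution. Non-convergence is reported via status flags with
best-effort parameters; a fit is marked unidentifiable when the Kd
standard error exceeds 10× the estimate or the Jacobian column for Kd is
degenerate (e.g. a flat thermogram). The c = n·M0/Kd diagnostic and its
1 ≤ c ≤ 1000 fittable window are exposed alongside. Affinity effects are
summarized as fold-changes Kd_variant/Kd_reference.

## 4. Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with recorded
ground truth and byte-identical regeneration under a fixed seed:

* **Genome/annotation** — i.i.d. background at a plant-like GC fraction
  (default 0.36) with non-overlapping AACNDN instances planted inside
  promoter windows (degenerate positions sampled uniformly). Spurious
  background matches are *allowed by design*: with a ~1%-per-position
  match probability they dominate any megabase genome, so census truth is
  established by the naive oracle over the emitted files, not by the
  planted list alone.
* **Methylome** — per-motif flags drawn at configurable rates (defaults
  0.1 / 0.005 / 0.015 for 5mC-pos3 / 6mA-pos1 / 6mA-pos2, echoing the
  observed ordering 5mC ≫ 6mA2 > 6mA1 in plant methylomes) plus
  background calls at 0.005 per valid strand-position. Truth records both
  the drawn and the effective (post-background) flags.
* **Interface fixtures** — see above.
* **Thermograms** — the forward model plus Gaussian heat noise.

Not emulated: chromatin/methylation autocorrelation, sequence composition
structure (the census logic is position-exact, not composition-sensitive),
full B-DNA duplex geometry, instrument baseline drift. Passing tests
therefore demonstrate correctness of the *computational* pipeline under
its stated conventions, not robustness to every artifact of real genomes,
crystal structures or calorimeters.

## 5. Problem sizes and numerical choices

The test suite and the acceptance script use a 1 Mb genome / 500 genes /
2000 planted motifs for the census check, 200 random cases (≤ 5 kb) for
scanner/oracle equivalence, and a 4 × 3 grid of (Kd, n) × 100 noisy
replicates at 1% heat noise for ITC recovery — sizes chosen to exercise
every code path at a scale a laptop handles in seconds while spanning the
experimentally reported affinity range (Kd ≈ 0.02–2.6 µM, c ≈ 8–1000).
Distances are reported to 0.01 Å (PDB coordinates carry 0.001 Å); census
counts are exact integers; fold-changes are plain ratios. Degenerate
inputs (empty genomes, empty contact lists, flat thermograms, all-gap
alignment columns) return empty/zero results or explicit flags rather
than raising.

## Known limitations

* Distance-only H-bond criterion can over-call contacts in dense
  interfaces; the cutoffs are exposed for tightening.
* The 5mC rule is a steric screen, not an energy model; it cannot rank
  partial sensitivity (e.g. Leu vs Glu at the reading position) beyond
  clash/no-clash.
* The census treats methylation calls as binary; fractional methylation
  levels enter only through the optional score filter.
* mmCIF input, crystallographic symmetry expansion and multi-model
  ensembles are out of scope for the PDB reader.
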