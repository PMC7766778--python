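# Methods notes

## Mass model

Peptide ions are treated as singly protonated monoisotopic species
(MH⁺ = Σ residue masses + H₂O + H⁺), the dominant form in positive-mode
MALDI-TOF; isotope envelopes, higher charge states and fragment ions are out
of scope. Constants (Da): water 18.010565, proton 1.007276, citrullination
(Arg→Cit deimination) +0.984016, phenylglyoxal condensation per citrulline
(C₈H₆O₂ − H₂O) +116.026215. Monoisotopic rather than average residue masses
were chosen because they reproduce all published unmodified MH⁺ values of
the fibrinogen peptides to 2 decimal places — including the γ-chain peptide
IHDVTGRDCQDVANK (computed 1670.7915 vs printed 1670.79), so no special-case
handling of that peptide is needed anywhere. No fixed cysteine modification
is applied by default (no alkylation step exists in the mapped workflow);
residue masses and constants can be overridden via YAML for workflows that
need fixed modifications.

The isoelectric-point solver bisects net charge = 0 under a
Henderson–Hasselbalch model with the classical EMBOSS pKa set (N-term 8.6,
C-term 3.6; D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5).
Citrullinated arginines are removed from the titratable census (the ureido
side chain is neutral). Absolute pI of short peptides is strongly
model-dependent, so the package and its tests assert only orderings — pI is
monotonically non-increasing in the number of citrullinations — never
absolute values.

## Digestion and candidate enumeration

Cleavage follows the Keil rule (C-terminal to K/R, not before P); chain
termini are always valid boundaries. Candidate enumeration distinguishes
three kinds of internal arginine:

- R at a cleavage position, citrullinated → **blocked** site: trypsin could
  not cut there, and it does not consume the missed-cleavage budget (the
  point of the PGM experiment is precisely that blocked sites and genuine
  missed cleavages are isobaric without derivatization);
- uncitrullinated internal K/R cleavage sites → missed cleavages, capped at
  `max_missed` (default 2);
- R before P → never a cleavage site, but still citrullinatable (mass
  relevant only).

A cleaved C-terminal R is never citrullinated (the cut could not have
happened); an R at the chain terminus may be. Citrullines per peptide are
capped at `max_cit` (default 3) to bound the combinatorics; the published
peptides need at most 2. The enumerator is verified against an exhaustive,
independently written invariant-checking oracle on random chains.

## Peak matching and site assignment

Default tolerance ±0.2 Da, consistent with the 0.02–0.19 Da observed-vs-
theory gaps typical of the source MALDI-TOF data; a ppm error is reported
alongside. Each peak takes at most one candidate, tie-broken by smallest
|error|, fewest citrullines, fewest missed cleavages, lowest start
coordinate. Candidates that survive all keys (exactly isobaric positional
isomers implicating different sites) are returned as a flagged ambiguity
group; ambiguous evidence never creates a site call. Note the
missed-cleavage key resolves the common one-citrulline-two-arginine case in
favour of the blocked interpretation of the cleavable arginine (e.g. the
β-chain 16–28 peptide's single-PGM ion is attributed to the arginine whose
citrullination explains why the peptide was not cut there). Site assignment
requires at least one unambiguous PGM-derivatized match covering the
position; `require_paired_native` additionally demands the underivatized
citrullinated ion of the same candidate (shift of exactly n_cit × 116.026).
Intensities are carried through but never scored. Per-run counts are
reported as-is; consolidating sites across repeat experiments is left to
the user.

## The worked-example fixture

The published record contains peptide-level data (spans, sequences,
observed m/z, MH⁺) but not the bovine chain sequences, so
`citmap.fixtures` rebuilds each chain as a **synthetic** glycine scaffold
with a lysine immediately before each printed span; every printed peptide
is then a legitimate tryptic product at its printed coordinates, and all
evidence flows through the normal theory path (no injected masses). The
PAD4-only β-chain peptide has no printed coordinates and is placed at an
arbitrary documented span (40–59) with its cleavable context. Conclusions
drawn from this fixture are about the pipeline's arithmetic and logic, not
about bovine fibrinogen biology: filler regions contribute only inert
poly-G peptides, far in mass from every observed ion.

## Expression modules

The DEG caller uses per-donor log2 deltas (fibrinogen − vehicle) with a
fold-change threshold (default 1.0 log2 unit) because the original
significance criterion is unstated and its raw arrays are not deposited;
the published gene counts are therefore not reproduction targets.
Concordance is strict: every donor must agree on the direction (a
majority-vote mode exists, off by default, and with only two donors it
coincides with strict). Module 2 requires opposition of the citrullination
delta (cit-fibrinogen − fibrinogen) to the fibrinogen direction by at least
the reversal threshold in every donor; genes whose citrullination delta
concordantly continues in the same direction are left unclassified, since
the underlying design reports that no fibrinogen-regulated gene was
concordantly further moved by citrullination. Remaining concordant UP/DN
genes become modules 1/3. The published K-means step is omitted: the
modules are defined directly by these rules, and genes that fit none stay
in an explicit `none` bucket rather than being forced into a partition.

## Enrichment

The running-sum (weighted Kolmogorov–Smirnov) enrichment score uses weight
1 by default; weight 0 reduces to the classical KS statistic, which the
test suite cross-checks against a brute-force implementation. The null is
gene-label permutation (random same-size gene sets) — phenotype permutation
is impossible with two donors. NES divides ES by the mean |ES| of the
matching-sign null; p and FDR-q are matching-sign tail fractions of the
null ES and null NES respectively (with a single gene set the standard
positive/negative-tail FDR degenerates to that tail probability; the
multi-set `enrichment_table` scores each set against its own null rather
than pooling across sets of different sizes, since pooled normalization is
only exchangeable for similar set sizes). When fewer than 10 same-sign
permutations exist the result falls back to a two-sided |ES| tail and
records a warning. Defaults: 1000 permutations, seeded generator,
bit-reproducible.

## Synthetic data

The spectrum simulator digests the chain as trypsin would see it after
citrullination of the planted sites (blocked cut sites), emits each
peptide's theoretical MH⁺ (PGM applied per citrulline) with Gaussian m/z
jitter (default σ 0.05 Da, a typical external-calibration MALDI-TOF error),
and adds Poisson-many uniform decoys over the observed m/z range. The
expression simulator plants module blocks (defaults: 10%/5%/10% of 2000
genes, mirroring the published proportions of regulated genes at desk
scale) on a N(8, 1.5) log2 baseline with N(0, 0.3) per-sample noise, effect
and reversal of 2.0 log2 units; module-2 directions are split randomly.
Neither simulator emulates isotope envelopes, matrix cluster ions, probe
effects or intensity-dependent noise — a green recovery test establishes
the correctness of the digestion/matching/classification logic under the
stated error model, not robustness to real instrument artifacts. Both are
bit-reproducible from (config, seed), and the truth records suffice to
score recall/precision/accuracy downstream.

## Known limitations

- Site evidence is purely mass-based; exactly isobaric positional isomers
  that no tie-break separates are surfaced as ambiguity groups, not
  resolved (MS/MS localization is out of scope).
- No FDR control on peak matching (no target–decoy search); the source
  workflow used manual spot-level interpretation.
- With two donors, strict concordance is the only meaningful mode; the
  classifier's accuracy guarantee is specific to the stated synthetic
  world (effects twice the threshold, σ 0.3).
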