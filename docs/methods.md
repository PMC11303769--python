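# Methods

This note documents the models, defaults and numerical choices behind
`enamelsex`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Peptide chemistry

Masses are monoisotopic throughout. Constants are pinned in one table
(`chem.py`): proton 1.0072765 Da, water 18.0105646 Da, isotopologue spacing
1.0033548 Da (¹³C–¹²C), residue masses from the standard amino-acid table at
five decimal places, residue elemental formulas over C/H/N/O/S (+P for
phosphopeptides). This precision reproduces all four panel reference m/z
values to four decimal places; property tests cross-check peptide masses
against an independent mass library to < 5×10⁻⁴ Da. I and L are distinct
letters of equal mass; no interconversion is assumed anywhere.

The modification registry ships seven entries (oxidation, di-oxidation,
deamidation, phosphorylation, N-terminal acetylation, Gln→pyro-Glu,
Glu→pyro-Glu), each with a mass delta and an elemental-composition delta
that must agree to < 10⁻⁴ Da. Di-oxidation is a distinct +31.989830 entry
rather than oxidation applied twice, so the "at most one modification per
position per name" invariant stays simple. Pyro-Glu entries are N-terminal
only and additionally constrain the first residue.

Isotopic envelopes aggregate isotopologues by nominal mass shift (A0, A+1,
…) via per-element convolution (exponentiation-by-squaring over
`np.convolve`), truncated to `n_peaks` and renormalized. Fine structure is
deliberately not modelled: at the resolutions relevant for ~1 kDa peptides
the nominal-mass aggregate is what an instrument reports. The default
`n_peaks = 4` covers > 99% of the intensity of peptides in this mass range.
Tests verify the convolution against exhaustive enumeration over
isotopologue combinations to 10⁻¹⁰ for random compositions of ≤ 20 atoms.

Fragment ions cover the b and y series, lengths 1..n (the full-length b_n /
y_n ions included), charges up to `max_charge`; position-resolved
modifications travel with the fragment containing their residue and
N-terminal modifications with the b series. a/c/x/z series and neutral
losses are out of scope.

## Marker panel

The default panel is the four-peptide AmelX/AmelY set with its published
reference m/z values; the loader recomputes each m/z from sequence +
modifications and refuses to load on disagreement > 0.002. The X1
methionine oxidation is fixed at peptide position 2 (the only Met).
SAAV positions are stored as documentation only — they are protein-
coordinate facts, not algorithm inputs.

Panel uniqueness is checked by exact (optionally ≤ 1-mismatch) substring
search against user-supplied AmelX/AmelY FASTA records, not by remote
homology search: the claim reproduced is panel-scoped ("each marker occurs
in its source protein and not in the homolog"), with no proteome-wide
guarantee. The shipped `synthetic_amelogenin.fasta` is a synthetic stand-in
whose marker-context coordinates match the documented SAAV positions; it is
not a database record, and users validating against real proteomes should
supply the curated sequences.

## Run model and formats

Runs are ordered collections of centroided spectra (strictly ascending m/z,
non-negative intensities, RT in seconds, MS2 spectra carrying precursor m/z,
charge and isolation half-width). Two formats are supported: a JSON-lines
internal format (plain-text, used for fixtures and simulator output; m/z
rounded to 6 decimals, intensities to 4 — below any tolerance used
downstream) and a minimal PSI-mzML subset. The mzML writer emits centroided
spectra with 64-bit m/z / 32-bit intensity arrays, uncompressed; the reader
additionally accepts zlib-compressed arrays and minute-based scan times
(normalized to seconds). Vendor formats, profile data, chromatogram elements
and ion mobility are out of scope.

## Synthetic run generator

The generator emulates the structure of the study's samples, not their raw
signals. Each species (marker peptide or partially deamidated background
peptide) elutes as a Gaussian: intensity apex·exp(−(t−t₀)²/2σ²), emitted as
its first four isotopologues per MS1 scan, with per-centroid Gaussian ppm
mass jitter and multiplicative intensity noise. Defaults: 600 s run, 1 s
scan interval, σ ≈ 2.55 s (6 s FWHM) — a compact stand-in for a 50-minute
gradient chosen so a full cohort simulates in seconds while preserving peak
shape, isotopic structure and DDA behaviour. Female samples force the AmelY
apex intensities to zero; marker apex defaults (10⁷–10⁸ counts) echo the
order of magnitude of reported male XIC intensities.

Deamidation is simulated per site, independently, at occupancy p_N / p_Q;
a peptide with k sites yields binomially weighted count channels (forms
below 0.1% of the peptide's intensity are pruned). Era defaults are modern
p_N = 0.20, p_Q = 0.10 and archaeological p_N = 0.60, p_Q = 0.50 — chosen to
give the severalfold modern-vs-ancient gap in the direction reported for
real material while remaining a controllable test quantity, not a claim
about true archaeological occupancies. The two default background peptides
each carry deamidatable sites of a single residue class (three Q or two N)
so MS1 count channels attribute unambiguously (see below).

DDA MS2: after each MS1 scan the top-10 peaks above 10⁵ counts (tie-break:
intensity descending, then m/z ascending) not on the 20 s dynamic-exclusion
list are "fragmented"; if a simulated species lies within the 0.85 m/z
isolation half-width its b/y ions are emitted with random intensities, plus
Poisson decoy peaks. Decoy MS1 peaks are uniform in m/z over 350–1650 with
exponential intensities (default 20 per scan at scale 10⁴).

Ground truth records the closed-form injected area apex·σ·√(2π) per species;
quadrature of the emitted signal reproduces it within 1% at the default scan
interval. Cohorts derive per-sample sub-seeds from the master seed via
`SeedSequence(master, spawn_key=(k,))`, so samples are independent streams.

What the generator does **not** model: peak tailing and RT drift,
co-isolation/chimeric MS2, protease (MMP20/KLK4) cleavage preferences,
inter-run RT variation, detector saturation, and real archaeological
backgrounds. Passing tests therefore demonstrate correctness of the
computational pipeline under idealized chromatography — not field
performance on degraded samples.

## Quantification

XIC extraction sums centroid intensities within ±10 ppm (MS1 default, per
the acquisition settings the method was developed with) of each
isotopologue m/z, per scan. When several known targets lie close together,
extraction supports nearest-target assignment: an observed centroid counts
toward a target only if that target is the nearest member of the competing
set. This matters for deamidation count channels at z = 2, where a channel's
monoisotopic peak sits only ~0.0097 m/z (≈ 14 ppm) above the previous
channel's A+1 isotopologue: without competition, mass-error tails leak the
larger channel into the smaller and bias occupancy upward.

Peak picking takes the global maximum of the monoisotopic trace (restricted
to ±30 s around the expected RT when one is supplied; ties resolve to the
earliest RT), extends bounds until intensity falls below 1% of the apex, and
integrates each isotopologue trace by the trapezoid rule. On noiseless
Gaussian peaks this recovers the closed-form area within 2% (the 1% boundary
cutoff forfeits < 0.3% of a Gaussian's area).

Detection combines three gates, each with its own `reasons` entry:

* **area floor** — area must exceed 10× (median out-of-peak summed-trace
  intensity × peak duration), plus an optional absolute `min_area`. The
  floor is relative because the underlying method reports presence/absence
  without a numeric LOD.
* **envelope score** — cosine ≥ 0.90 between observed and theoretical
  isotopologue vectors. A single-channel chance XIC hit scores ≈ 0.9 or
  less for peptides in this mass range, which is what keeps the empirical
  AmelY false-positive rate at zero on female-spec runs.
* **MS2 validation** — ≥ 4 distinct b/y ions (charges 1–2) within 20 ppm in
  the best MS2 spectrum whose precursor matched the marker within the
  isolation half-width. Runs (or markers) without any targeting MS2
  spectrum are treated as MS1-only: the gate reports "not evaluated" and
  does not block detection.

Areas are linear in input intensity by construction (every step is a sum or
trapezoid), which tests assert exactly.

## Deamidation statistic

Bulk occupancy is the intensity-weighted site-level fraction
Σ areaᵢ·n_deamidatedᵢ(X) / Σ areaᵢ·n_sitesᵢ(X) per class X ∈ {N, Q} —
site-weighted rather than per-peptide-averaged so that forms with unequal
site counts do not bias the estimate. No signal yields a missing value,
never 0. The classes are Asn and Gln (the residues that chemically
deamidate); Arg deamidation (citrullination) is excluded from the bulk
statistic. Count channels that share a total deamidation count are isobaric
at MS1, so run-level estimation requires background peptides whose sites are
all one class; mixed peptides raise an explicit error rather than returning
a biased split. Channels failing the envelope gate are excluded. The
modern-vs-archaeological comparison is a descriptive ratio of group means
per class (missing values skipped; zero baseline flagged as infinite) — no
hypothesis test, since the quantity of interest is the fold itself.

## Classification

The call is a presence/absence rule: indeterminate without AmelX evidence
(enamel recovery control), male on ≥ 1 detected AmelY marker (high
confidence on both — a two-tier call that preserves sensitivity while
flagging single-marker males for review), else female (high confidence on
both AmelX markers). No X:Y intensity ratio enters the decision. The rule is
monotone: added AmelY evidence can only move a call toward male.

## Problem sizes and determinism

Default test and acceptance workloads use 600 s × 1 Hz runs; cohort checks
use 8-sample (4M/4F) modern and 12-sample (6M/6F) archaeological designs
over 10 master seeds, occupancy recovery uses p ∈ {0.1, 0.3, 0.6, 0.9} × 10
seeds, and the false-positive check uses 20 female runs — sizes chosen so
the full suite completes in well under a minute while every statistic is
estimated from multiple independent streams. All randomness flows from
explicit integer seeds; identical specs and seeds produce byte-identical
internal-format output.

## Known limitations

* Quantification assumes the panel *is* the identification; there is no
  spectral search, FDR machinery, or retention-time alignment across runs.
* The envelope gate assumes centroided, resolved isotopologues; profile
  data are out of scope.
* Occupancy estimation is bulk (per residue class), not positional, and
  requires single-class background peptides at MS1.
* The synthetic generator's idealizations listed above mean real-data
  performance claims require real runs; the package reads standard mzML for
  that purpose.
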