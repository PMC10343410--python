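# Methods

## Exact-mass model

All m/z arithmetic is monoisotopic and singly charged. The element table is
embedded (H 1.0078250, C 12 exactly, N 14.0030740, O 15.9949146, plus
S/P/Na/K/Cl/F) so that core math has no runtime dependency. The charge
carrier is the proton: (de)protonation shifts mass by ±1.007276 Da (the
hydrogen atom minus the electron), the water-loss adduct by
−18.010565 + 1.007276 Da, and ammonium adduction by +18.033826 Da (N + 4H −
e⁻). These conventions reproduce the theoretical m/z of all 29 compounds in
the identification table to ≤ 0.002 Da, and the six anchor compounds
(citric acid, leucine, quercetin, rutin, verbascoside, ellagic acid
glucoside) to the printed 4 decimals. Two table rows (oleic acid,
pyroglutamic acid) disagree with their formulas by 0.8–1.8 mDa and are
carried as printed, treated as typesetting artifacts rather than silently
corrected; norvaline's printed experimental m/z is ~0.022 Da from its
formula and the fixture plants the theoretical value instead.

Formula parsing accepts plain Hill notation, Unicode subscripts and the
underscore dialect of typeset tables, normalising all three to canonical
Hill strings. Isotope patterns, multiple charging and radical ions are out
of scope.

## Virtual-metabolite enumeration

Scaffolds are combined with 0–2 glucose units and 0–1 methyl groups (both
limits configurable); the (0, 0) combination is the hydrogen block that
retains the parent. Mass bookkeeping is condensation chemistry: +C₆H₁₀O₅
per glucose and +CH₂ per methylation — the chemically standard choice,
which also reproduces the C₂₀H₁₆O₁₃ composition of ellagic acid glucoside.
SMILES strings are carried through untouched; no attachment-site chemistry
or valence checking is attempted, because masses and diagnostic ions, not
structures, drive every downstream decision. For enumerated glycosides the
predicted fragmentation is reduced to diagnostic ions: the deprotonated
aglycone (parent plus any methyls) and neutral losses at integer multiples
of 162.0528 Da, plus a labelled sugar-moiety ion.

The study fixture enumerates seven scaffolds: the six compounds common to
the virtual-metabolite and literature lists (quercetin, kaempferol,
apigenin, gentisic acid, gallic acid, chlorogenic acid) plus ellagic acid,
whose glucoside is the one enumerated compound that is actually identified.
The parent ellagic acid is carried on the bioactivity-driven list, not the
literature list, which keeps the cross-list intersection at exactly those
six compounds.

## Synthetic runs

Chromatographic peaks are Gaussian: apex RT, area and sigma per compound
(default sigma 0.05 min; the study fixture uses 0.04 min so the 0.1-min RT
grid of the early organic-acid cluster — citric/malic at 1.2 min,
fumaric/quinic at 1.3 min — is resolved). MS1-level scans carry one peak
per eluting compound at its experimental m/z plus ~20 uniform-random noise
peaks per scan (intensity ≤ 30 counts against peak heights of 10⁵–10⁷).
DDA runs trigger one MS2 scan at the apex of each of the 10 most intense
precursors, containing the compound's fragments at a rank-decreasing
intensity profile (100/80/60/40/20) scaled to half the precursor apex. DIA
runs alternate low-energy survey scans with high-energy scans containing
the superposed fragments of everything co-eluting. Scan interval 0.01 min,
gradient 14.5 min, seeded; identical seeds give byte-identical runs.

What the generator does *not* emulate: peak tailing, ion suppression,
matrix effects, isotope envelopes, and real fragment intensities (the study
publishes fragment m/z but not intensities — the rank-decreasing profile is
shared between "sample" and "library" spectra, so cosine scores come out
near 1 and the tests exercise the 0.7/0.6 gate logic, not instrument
physics; the printed per-spectrum total scores of 0.6–0.99 are consequently
not reproduction targets). Because no isotope peaks exist, level-4 formula
confirmation rests on exact-mass fit alone — a documented divergence from
common practice.

Areas are constructed, not published: they follow the reported abundance
patterns (ethyl gallate lower with more secondary juice, quercetin higher,
fructose flat) and place the organic-acid cluster in the DDA top-10 so the
co-eluting 1.2/1.3-min acids take the clean DDA route, matching the
described practice of reserving DDA for the most abundant compounds. Two
synthetic contaminant probes are planted with blank areas one-third of the
sample areas (all genuine compounds sit at one-tenth), so the five-fold
blank rule must exclude exactly them; two genuine compounds are absent from
the blank to exercise the keep-on-absence branch.

## MS1 screening

EICs sum intensity in an absolute ±0.005 Da window (the mass-accuracy bound
the identification table states); ppm windows are deliberately not used.
Peak detection takes local maxima above 3× a robust noise scale (1.4826 ×
MAD), requires ≥ 3 consecutive above-threshold points (a single-scan spike
is not chromatography), and bounds peaks at descent to 5 % of apex or a
local minimum; areas are trapezoidal over the bounds, which recovers ≥ 98 %
of a planted Gaussian's area. The blank filter matches features by suspect
identity and |ΔRT| ≤ 0.2 min and keeps a feature iff no blank counterpart
exists or sample area ≥ 5 × blank area.

## Fragmentation matching

DDA: the MS2 scan whose isolated precursor lies within 0.005 Da and whose
RT is nearest the feature's bounds centre. DIA: a pseudo-spectrum is
assembled from the high-energy scans inside the feature's RT bounds — every
fragment channel (clustered at the 0.01 Da fragment tolerance) enters iff
its trace has ≥ 3 nonzero points, its apex lies within 0.1 min of the
feature apex, and its Pearson correlation with the precursor trace is
≥ 0.8. This correlation gating is a deliberately simple, testable
pseudo-spectrum construction in the spirit of DIA deconvolution algorithms,
not a reimplementation of them; fragments of compounds eluting ≥ ~0.3 min
away are rejected by the apex/correlation gates, while exact co-elution
within the apex window contaminates the pseudo-spectrum and lowers the
cosine — which is why the exactly co-eluting acids are routed through DDA.

Similarity is the plain intensity cosine over greedily matched peak pairs
(smallest |Δm/z| first, one-to-one, ±0.01 Da): no m/z weighting, since none
is specified for the workflow being modelled. Unmatched peaks contribute to
the norms only. On well-separated spectra the greedy pairing equals the
optimal assignment (property-tested against brute force).

## Confidence levels

Rules fire in order of evidence strength: level 1 needs an available
reference standard, |RT − standard RT| ≤ 0.5 min and cosine ≥ 0.6 against
the standard's spectrum; 2a needs a library cosine strictly > 0.7; 2b all
diagnostic ions present; 3 at least half of the supplied in-silico
fragments matched; 4 formula confirmed (here: exact-mass fit); 5 exact mass
only. The 0.5-min RT tolerance covers the largest printed
standard-vs-observed gap (apigenin, 0.4 min); the 0.6 level-1 gate reflects
that standard-confirmed identifications are reported with scores as low as
0.61, while the strict 0.7 gate applies to library matches only. Predicted
retention time is carried as metadata and used only for prioritisation,
never as a hard filter. Suspects with the same formula, polarity and
retention time (within 0.2 min) are exact-mass indistinguishable isomers:
one primary (strongest evidence, then lexicographic) is reported and the
rest become co-candidates — in the fixture this collapses the enumerated
kaempferol diglucoside (C₂₇H₃₀O₁₆) onto rutin's feature.

## Quantification

Unweighted ordinary least squares on the five working-solution levels
(0.5/1/2.5/5/10 mg/L); parameter standard errors from the classical OLS
formulas; inversion x = (y − b)/a; replicate mean and sample SD (ddof = 1);
LOQ flagging at 0.5 mg/kg applied to the final concentration. The
mg/L → mg/kg conversion is an explicit factor defaulting to 1 (the fixture
is self-consistent under that identity mapping; the 200 mg + 200 µL
preparation would imply a factor near 2 for real extracts, which users set
via `prep_factor`). Fixture replicates are generated at concentrations
(c − s, c, c + s) for a reported mean c and SD s, which reproduces both
exactly with zero noise; the noisy variant adds 2 % relative Gaussian noise
to calibration responses (seeded), keeping R² ≥ 0.97 as reported for the
validated method. Cells reported only as "< LOQ" are encoded at 0.3 mg/kg,
below the limit and with all responses positive, and a synthetic
catechin-style analyte exercises the below-LOQ path.

## Problem sizes and determinism

The synthetic study is 14 runs (3 juices × 2 polarities × 2 acquisition
modes + 2 blank runs) of ~1.5–3 k scans each, screened against ~65 merged
suspects; generation plus the full pipeline takes a few seconds on one
core, and every stage is deterministic under the configured seed (derived
per-run seeds are seed × 1000 + run index). The one mzML reader/writer pair
covers the centroided subset of the format the tool needs (spectrum
cvParams, precursor isolation, collision energies, 32/64-bit float arrays
with optional zlib); vendor raw formats and profile data are out of scope,
and profile-mode files are rejected rather than centroided.

## Known limitations

* Identification logic is only as good as the suspect lists; nothing
  untargeted is detected.
* The DIA pseudo-spectrum stand-in fails for exact co-elution (by design it
  then contaminates, and routing falls back to DDA abundance ordering).
* Level 4 without isotope scoring overstates formula confidence on real
  data; on the fixtures it is exercised only by isomer co-candidates.
* Cosine magnitudes on the fixtures are near 1 by construction and say
  nothing about real spectral similarity; only the gate logic is validated.
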