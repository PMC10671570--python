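# Methods

`osptm` implements the downstream half of an open-search PTM experiment:
everything that happens after a wide-precursor-tolerance database search
has produced a table of peptide-spectrum matches (PSMs) with delta
masses. The pipeline has six stages — delta-mass recalibration and peak
modelling, target-decoy FDR at three levels, catalog/composite
annotation, residue and sequence-quintile specificity, modified-protein-
site (qdna) aggregation and standardized spectral-count quantitation,
and correlation-network response clustering — plus a synthetic-data
generator that stands in for the spectral search.

## Delta-mass peaks

Each PSM carries ΔM, the experimental precursor mass minus the
theoretical mass of the unmodified peptide candidate. Across an
experiment, ΔM values pile up into narrow peaks, one per modification
(plus isotope satellites at k·1.003355 Da).

**Recalibration.** Per sample, the median ΔM of the unmodified
population (|ΔM| < 0.05 Da) is subtracted from every ΔM of that sample.
Samples with fewer than 50 anchor PSMs are left uncorrected with a
warning. This is a deliberately simple constant-offset model; published
recalibration pipelines can be m/z-dependent, which is out of scope
here.

**Peak modelling.** ΔM values are histogrammed on a 0.0005 Da grid and
smoothed with a Gaussian kernel (bandwidth 0.005 Da, of the order of the
instrument's mDa accuracy). Local maxima of the smoothed density
supported by ≥ 5 PSMs become peaks; boundaries sit at the flanking
density minima, so peaks never overlap and assignment is unambiguous.
The apex is the mean ΔM of the member PSMs. Isotope satellites remain
separate peaks at this stage; `collapse_isotopes` maps a satellite onto
a parent when the apex difference is k·1.003355 ± 0.01 Da (k ≤ 3) and
the parent carries more PSMs — the count condition makes the relation
acyclic.

**Three-level FDR.** Target-decoy q-values are computed in three
strata: globally, within each 1-Da ΔM bin, and within each ΔM peak.
Within a stratum, FDR(s) = #decoys(score ≥ s) / #targets(score ≥ s),
monotonized to q-values by a cumulative minimum from the score-sorted
tail; at tied scores decoys rank above targets (conservative). A PSM
passes only if all three q-values are ≤ 0.01. PSMs outside every peak
cannot pass: only peak-supported identifications are validated. A
stratum without decoys yields q = 0 with a warning.

## Annotation and composite arithmetic

A peak is annotated by catalog entries within 0.01 Da of its apex
(the catalog reports several masses at two-decimal precision, so the
tolerance must be at least half a unit in the last printed place).
Unknown shifts are decomposed into composites: every multiset of ≤ 3
catalog entries, optionally plus k ≤ 3 isotope spacings, whose summed
mass lands within 0.005 Da of the target, enumerated exhaustively and
ranked by |error|, then fewer components, then name. Gains and losses
mix freely — e.g. Met loss (−131.040485) + N-terminal acetyl
(+42.010565) + phospho (+79.966331) = −9.063589 ≈ the −9.06 Da shift.
One printed identity is arithmetically inconsistent at two-decimal
precision (0.98 + 0.98 − 17.02 = −15.06, not −15.04); with precise
masses the intended composite (one C13 + deamidation + ammonia loss =
−15.039) does match, and the implementation follows precise masses.

## Specificity and origin calls

For each peak, the **residue profile** gives raw(a) = % of modified PSMs
carrying the shift on residue a, minus a background: the frequency of a
among the up-to-six flanking positions (offsets ±1..±3 around the
modification site), averaged per PSM and then over PSMs. Offsets falling
outside the peptide are dropped from the average rather than padded,
which would bias short peptides. The **quintile profile** places the
modified position into fifths of the peptide sequence,
quintile = ⌊5(pos−1)/L⌋ + 1.

**Origin.** A shift concentrated (> 70%) in the first quintile of
peptides that do *not* start their protein is called artefactual — it
sits on the newly generated peptide N-terminus, the signature of bench
chemistry (e.g. ammonia loss from N-terminal carbamidomethyl-Cys).
First-quintile concentration on protein-N-terminal peptides is
biological (Met loss, N-terminal acetylation), so those PSMs are
excluded from the test; if fewer than 5 internal-peptide PSMs remain,
no artefactual call is made. Peaks with fewer than 10 modified PSMs are
"unknown" — percentage estimates below that are unstable.

## Sites and quantitation

A modified protein site (qdna) is the tuple (protein q, peak d,
position n = peptide_start + mod_pos − 1, residue a). All peptidoforms
covering the same qdna — full tryptic and missed-cleavage partials —
merge into one element; the same position under a different ΔM peak is
a different element. Site identity uses the peak id, not the raw ΔM
float; satellite peaks can optionally be merged into their parent's
site (`merge_isotope_sites`, off by default, on in the pipeline's
response-clustering configuration so the isotopic envelope of a site is
counted once). PSMs whose claimed residue disagrees with the protein
sequence are rejected and logged; decoy-protein PSMs never form sites.

**Partial-digestion filter.** Glycerophosphorylation flips the charge
of lysine and blocks tryptic cleavage there, so a genuine pgK peptide
must be a partial-digestion product. For peaks annotated as
charge-switching Lys modifications (and their satellites), PSMs whose
modified K is the peptide C-terminus are contradictory and removed.

**Standardized spectral counting.** With X(e, s) the PSM count of
element e in sample s and T(s) the sample's total PSM count:

    F(e, s) = (X(e, s) + 0.5) / T(s)
    R(e, s) = log2( F(e, s) / median_s' F(e, s') )
    Z(e, s) = ( R(e, s) − mean_e R ) / SD_e R        (per sample)

The 0.5 pseudocount keeps log2 finite at zero counts. The
median-of-all-samples reference is conservative: an element behaving
like the cohort median has R = 0 even when a minority of samples carry
a group effect. Elements are quantified only if their summed PSM count
strictly exceeds 15 and (by default) every sample has ≥ 1 PSM.

**Protein normalization.** Site changes independent of protein-level
changes are isolated as Zq_qdna: the site's log2 ratio minus its
protein's log2 ratio, re-standardized per sample. The subtraction
happens on the log2-ratio (R) scale, where site and protein are
commensurable. Subtracting the z-score layers instead is tempting but
wrong: Z is standardized within different element populations (sites
vs proteins), and dividing a mild protein trend by the proteins' small
per-sample spread manufactures a large correction that erases genuine
site effects — we observed exactly this failure on synthetic data
before settling on the R-scale form.

## Response clustering

Sites whose Zq_qdna profiles have Pearson r > 0.5 across the nine
samples are connected in a weighted graph (weights = r; negative
correlations never create edges). Clusters maximize the cohesiveness

    f(V) = W_in / (W_in + W_bound + p·|V|),   p = 2,

grown greedily from seeds in descending weighted-degree order (adds and
removals both considered), merged in a single pass when the overlap
score |A∩B|²/(|A||B|) ≥ 0.8, and discarded below 5 members. An isolated
5-clique of unit edges scores exactly 10/(10 + 0 + 10) = 0.5.
Significance is a one-sided Mann–Whitney test of internal versus
boundary edge weights; a cluster with no boundary edges is maximally
separated and reported with p = 0. Cluster response distributions are
compared to the all-site background by the two-sample
Kolmogorov–Smirnov test (exact when n·m ≤ 10⁴).

## The synthetic-data generator

The generator emulates a phosphopeptide-enriched open-search experiment
over a 3-group × 3-replicate design (control, 3 and 12 weeks of
high-fat diet):

* a 25-protein random proteome (length ~ N(360, 80²) aa, combined K/R
  density 0.12, all proteins starting with Met), digested with the
  combined trypsin/LysC rule (cleave after every K or R, up to 5
  missed cleavages, products of 7–35 aa observable);
* ~12,000 PSMs per sample: 15% decoys (reversed-sequence proteins),
  15% false targets sharing the decoy score distribution N(0, 1) while
  true targets score N(3.5, 1) — equal decoy and false-target mass so
  target-decoy estimation has the right calibration; of the true
  targets, fixed budgets go to artefact entries (8%, placed at peptide
  position 1), a protein-N-terminal acetylation control (2%, placed on
  protein-initial peptides), and modified sites, with the unmodified
  bulk absorbing the remainder so that protein-level counts are
  dominated by unmodified peptides, as in real data where one site's
  peptidoforms are a small share of a protein's PSMs;
* modified sites: two planted response modules of 10 sites each
  (glycerophosphoryl-Lys falling to −1 log2, phospho rising to +1 log2
  along the diet course, half effects at 3 weeks; ~50 expected
  PSMs/sample each, the scale of an abundant PTM site) over a flat
  background of ~46 sites with lognormal abundances (median 8
  PSMs/sample); counts are Poisson (negative binomial optional);
  charge-switching Lys sites are only emitted on peptides where the
  modified K is internal;
* ΔM = catalog mass + k·1.003355 (k = 0, 1, 2 with probabilities 0.82 /
  0.13 / 0.05) + N(0, 0.003 Da) noise, plus a per-sample calibration
  offset N(0, 0.001 Da) for the recalibration stage to remove.

Everything is deterministic under the config seed (byte-identical PSM
tables).

What the generator does **not** emulate: fragment spectra and search
engine behaviour, retention time, intensity-based abundance, peptide
ionizability differences, co-eluting chimeras, and — importantly —
biological covariance among background sites. Background profiles are
independent Poisson noise, so any apparent correlation between a
background site and a planted module is a finite-sample accident.
Passing tests therefore show that the statistics behave correctly under
the stated model, not that real tissue data will be as clean.

## The clustering benchmark

With only nine samples, a background site whose noise happens to tilt
along the group axis correlates > 0.5 with every module member at once
(P ≈ 8.5% per site under the null), so grown clusters on the full
pipeline dataset legitimately absorb a few such sites. Module recovery
is therefore benchmarked on a direct planted-partition construction at
the quantitation level (`planted_response_matrix`): 15- and 12-site
anti-correlated modules over 23 flat background sites — proportions
scaled down from the reported response clusters, which hold a large
share of the network — with iid Gaussian noise of 0.2 log2 units (the
counting noise of a ~50 PSM/sample site). Recovery is scored as the
Jaccard index between each planted module and its best-matching
cluster, averaged over replicate matrices; the full-pipeline run is
additionally checked for correct response signs and significance of
the recovered clusters.

## Numerical choices and degenerate inputs

* Peak grid step 0.0005 Da; apex = mean of member ΔMs; a detected
  maximum whose members fall below `min_psm` is discarded and its PSMs
  stay unassigned.
* Composite enumeration is capped (default 2·10⁶ candidate
  combinations) and errors with advice rather than hanging.
* `quantify` refuses zero sample totals and zero per-sample variance;
  `correlation_network` excludes zero-variance profiles with a log
  message rather than emitting NaN edges.
* Clustering is deterministic: seeds in descending weighted degree,
  ties broken by label; candidate adds/removals are scanned in sorted
  order.
* Sample and site orderings are sorted everywhere results are
  assembled, so outputs are stable across runs.

## Problem sizes

Default analyses run on ~110,000 PSMs (9 × ~12,000), 25 target
proteins, ~66 planted sites and ~29 ΔM peaks; the clustering benchmark
uses 50-site matrices with 10 replicates. These sizes keep a full
pipeline run in a few seconds while leaving every statistic (FDR,
effect recovery, classification, clustering) comfortably estimable.

## Known limitations

* The recalibration model is a per-sample constant; mass-dependent
  drift is not corrected.
* Site positions come from the search engine's best placement; no
  localization scoring (Ascore-like) is attempted.
* The pgK filter implements the minimal reading — modified K must not
  be the peptide C-terminus; it does not additionally require a missed
  cleavage elsewhere.
* "Minimum density" of the clustering is reported as "Auto" by the
  original tool with no published numeric value; here a weighted
  density threshold (2 W_in / |V|(|V|−1)) defaults to 0.3 and is
  configurable.
* KS contrasts are reported member-vs-background; member-vs-control
  group contrasts can be formed from the exported group means.
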