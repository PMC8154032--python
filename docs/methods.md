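# Methods

## Coordinate model

Substrates are synthetic polypeptides excised from a protein, so all
coordinates are kept in full-protein numbering (1-based, inclusive) and
each substrate stores the protein coordinate of its first residue as an
offset. A cleavage product `P(i, j)` has length `j − i + 1`; a splice
product `SP(i, j, k, l)` is the acceptor `P(i, j)` ligated N-to-C to the
donor `P(k, l)` and has length `j + l − i − k + 2`. Order classes partition
the coordinate space: *normal* if `j < k`, *inverse* if `l < i`,
*overlapping* if `max(i, k) ≤ min(j, l)`; *trans* products take the donor
from a second substrate molecule. Single-residue fragments are allowed
(`i ≤ j < k ≤ l` rather than strict inequalities throughout), because the
minimum fragment-length parameter MinP = 1 must be expressible.

## Enumeration rules and their rationale

Candidates satisfy fragment-length bounds MinP ≤ part ≤ MaxP, total-length
bounds MinS ≤ length ≤ MaxS (epitope-sized windows for HLA class I/II
screens), and gap bounds on the residues skipped between the fragments:

* normal order: gap `k − j − 1` in `[max(MinG, 1), MaxG]`. The lower bound
  is never 0 because a contiguous pair (`j + 1 = k`) is literally the
  cleavage product `P(i, l)` and must not enter the database as a splice
  candidate.
* inverse order: gap `i − l − 1` in `[MinG, MaxG]`. Gap 0 is legitimate
  here — an adjacency ligated in inverse order is a sequence rearrangement,
  not a substrate substring — so only the user's MinG restricts it.
* overlapping and trans products carry no gap constraint (for trans a gap
  is undefined across molecules).

Products whose sequence occurs contiguously in the substrate are optionally
suppressed: MS cannot distinguish them from ordinary proteolysis, so they
only inflate the database. Equal-sequence products at *different*
coordinates are all retained — downstream fragment-level evidence (which
constituent fragments were actually observed) can favor one coordinate
version over another. Output order is deterministic (total length,
acceptor length, acceptor start, donor start) so database builds are
byte-reproducible.

Enumeration streams records one at a time; nothing requires the database in
memory. The analytic size predictor exists to decide *whether* to
enumerate: the unrestricted splice-product space of a length-L substrate is
`(L(L+1)/2)²` ordered fragment pairs (25,502,500 at L = 100, ≈3.6 GB at the
FASTA grammar used here), while restricted counts replicate the enumeration
rules in closed-form sums over part lengths and gaps. The predictor
matches the enumerated count exactly whenever the substring filter is off;
the filter itself depends on the actual sequence and is deliberately not
predicted. The estimated byte size assumes this package's header grammar
and is informational only.

## Mass arithmetic

Monoisotopic masses throughout (high-resolution Orbitrap data): neutral
mass = Σ residue masses + 18.010565 Da (water); `m/z = (M + z·1.007276)/z`.
The residue table is stated to 5 decimals and is verified in the test suite
against an independent atomic-composition oracle (pyteomics) to 1e-4 Da.
Chemical modifications are (name, Δmass, max copies) triples added to the
theoretical mass; oxidation (+15.99491 Da) ships as the only default.
Theoretical MS/MS uses b/y ions only (the dominant CID/HCD series);
masses are formatted at 5 decimals in FASTA output.

## Peak detection and assignment scoring

Intensity profiles are decomposed greedily: the most intense remaining
point seeds a single-Gaussian least-squares fit on a local window (bounded
where the signal falls below 10 % of the apex), the fit is subtracted, and
the residual is searched again. Fit R² is the goodness criterion; peaks
under the floor (default 0.8) are retained but flagged unreliable.
Overlapping-peak handling by residual refitting is a deliberate
simplification — heavily fused peaks are better deconvolved upstream.

Peak lists are filtered by a noise threshold (user-defined; default 3× the
median intensity of the list). Candidates match a peak when some
configured charge state lies within the precursor tolerance; instrument
presets are `orbitrap-xl` (10 ppm precursor, 0.6 Da ion-trap / 0.06 Da
Orbitrap fragments) and `q-exactive` (6 ppm, 0.02 Da; the default).

The assignment likelihood combines the four stated criteria as a weighted
sum, each component in [0, 1]:

| component | definition | default weight |
|---|---|---|
| mass | `1 − |ppm error| / tolerance`, floored at 0 | 0.35 |
| charge | fraction of configured charge states seen as co-eluting peaks at the candidate's other m/z values (within the RT window, default 1 min) | 0.15 |
| rt | 1 within the reference-RT window, exponential decay outside; 1 when no synthetic-standard RT is available | 0.15 |
| msms | fraction of theoretical z = 1 b/y ions matched within the fragment tolerance; 0.5 (neutral prior) without MS/MS | 0.35 |

Acceptance threshold 0.6. No canonical combination rule exists for these
criteria; this weighted sum is one defensible instantiation — monotone in
every criterion, fully configurable — and the defaults weight the two
high-information channels (mass, MS/MS) equally. "Occurrence of expected
m/z values" is implemented as charge states only, not isotopologues.

Assignment proceeds in three phases per peak list, each consuming only
still-unexplained peaks: (1) conventional cleavage products; (2) modified
peptides, accepted only if the unmodified sequence was accepted in phase 1;
(3) splice products, accepted only if both constituent fragment
*sequences* appear in the phase-1 accepted set. Fragment evidence is
checked by sequence (not coordinates), matching how a cleavage map is
read. Ties on one peak resolve by total score, then |ppm error|, then
lexicographically smallest sequence, making runs deterministic.

## Artifact audits

*t = 0 screen.* Before digestion no splice product can exist, so any
splice-database match in the undigested substrate's spectrum is flagged as
a pre-existing contaminant with its charge and ppm error.

*Deletion-variant audit.* Solid-phase synthesis of hydrophobic substrates
produces deletion byproducts; normal proteolysis of such a variant can
mimic a splice product exactly. A candidate is *ambiguous at d_max* if its
sequence occurs contiguously in the substrate with ≤ d_max residues
deleted. The implementation anchors the candidate at each substrate
position and matches greedily left-to-right (earliest match minimizes the
span and hence the deletion count for that anchor); the test suite checks
it against an exhaustive deletion-set oracle. By construction every
normal-order cis product with gap g is ambiguous at d_max ≥ g — deleting
exactly the gap residues reproduces it — which is why the audit matters
most for inverse-order candidates, where a clean result is informative.

## Synthetic data generator

The generator emulates a centroided LC-MS1 run of a digest: each planted
peptide contributes one peak per charge state at its theoretical m/z with
Gaussian relative jitter, intensity = abundance × charge probability, and
a fixed elution RT; uniform-random noise peaks are added across the scan
range. Defaults are a Q-Exactive-style acquisition: scan range 200–2000
m/z, gradient window 3–85 min, charge states 1–3 uniform, m/z jitter 3 ppm
(half the 6 ppm precursor tolerance), planted per-charge intensity 1e6
against noise ≤ 1e5 (SNR ≥ 10), 20 planted peptides and 200 noise peaks
per run. An accompanying MS/MS dictionary supplies the full z = 1 b/y
ladder for each planted peak, and a truth table attributes every non-noise
peak to exactly one (peptide, charge). Everything derives from a single
integer seed; identical seeds give bit-identical output.

The generator does *not* model isotope envelopes, chromatographic peak
shape (centroids only), RT prediction, ion suppression, or co-isolation.
Consequently, passing recovery tests demonstrate the correctness of the
matching/scoring/tier logic under calibrated conditions, not performance
on real digests, where isobaric interference and intensity-dependent mass
error are harsher. The faulty-synthesis sampler draws deletion variants
with independent per-position deletion events (correct-product frequency
`(1−rate)^L`), which suffices to build contaminated t = 0 fixtures but is
not a chemistry model of coupling failure.

## Numerical and design choices

* Problem sizes in the test suite are chosen for exhaustive verifiability:
  oracle-equivalence tests run ≥ 200 random substrates of ≤ 12 residues
  against a naive double-loop enumerator, where the full fragment-pair
  space is small enough to brute-force.
* Record masses are exact sums of table values; FASTA round-trips preserve
  coordinates exactly and masses to the printed 5 decimals.
* Affinity filtering consumes a precomputed peptide → IC50 (nM) table
  (external HLA binding predictors are trained models, used here only
  through their output); peptides absent from the table are dropped with a
  warning rather than silently kept.
* Degenerate inputs: unachievable enumeration constraints yield an empty
  stream, not an error; an empty peak list yields no assignments; the
  Gaussian fitter falls back to moment estimates when least squares fails
  to converge.

## Known limitations

Two-fragment splicing only (no multi-splice), no proteasome cleavage-site
preference scoring, no isobaric I/L disambiguation, no FDR estimation, no
vendor raw-file parsing (peak lists are TSV, MS/MS JSON). MS1-level
matching cannot separate sequence permutations of equal mass; the MS/MS
score is the only discriminating channel provided.
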