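# Methods

## Data model

An STR allele is written `<repeats>` or `<repeats>.<digit>`; the single
digit counts extra bases beyond whole repeat units (a *microvariant*).
Alleles compare exactly: `27`, `27.2` and `26.2` are three different
alleles. Ordering is lexicographic on `(repeats, microvariant)` with the
integral allele before its own microvariants; this ordering is used for
display and for range bounds.

A genotype is the **set** of distinct alleles observed at a locus. Set
semantics is the load-bearing choice of the whole package:

- a homozygous locus prints one value and contributes **one** allele to
  profile totals (not two — the typing assay cannot distinguish two copies
  of the same allele from one);
- a locus with three or more distinct alleles (an amplified region, or a
  contaminated culture) contributes each distinct allele.

Both conventions are required to reproduce the published reference scores
bundled with the package: the AT-3 comparison only yields 82.93% with
totals 20 and 21 counted this way, and MS1's tri-allelic marker 17-2 must
contribute three alleles to reach 78.05%.

A profile maps marker ids to genotypes. An untyped marker and a marker
mapped to the empty genotype are deliberately indistinguishable: the source
tables give no way to tell "not assayed" from "assayed, nothing called",
so both mean "no information at this locus". Marker labels are normalized
to ASCII hyphens on input (typeset tables use en-dashes: `1–1` → `1-1`).

## Scoring

With allele sets $Q_m, R_m$ over a marker set $M$:

- Tanabe: $100 \cdot 2\sum|Q_m \cap R_m| \,/\, (\sum|Q_m| + \sum|R_m|)$ — symmetric;
- Masters vs. query: $100 \cdot \sum|Q_m \cap R_m| / \sum|Q_m|$;
- Masters vs. reference: $100 \cdot \sum|Q_m \cap R_m| / \sum|R_m|$.

Marker-set modes: `non_empty_both` (default — markers with at least one
allele in *both* profiles), `query_markers`, `all_panel`. The default mode
matches the behaviour of the standard online matching tool: the packaged
comparison table omits marker 9-2 from every database line even though the
query types it, and all six reproducible scores follow only under the
both-non-empty reading.

Scores keep full precision internally; reporting rounds **half-up** to a
configurable number of decimals (default 2), matching how percent matches
are conventionally printed. Python's built-in banker's rounding would
differ on exact ties, so rounding goes through `decimal`.

A comparison with zero usable markers raises an error rather than scoring
0%: a zero would read as positive evidence of non-identity, when in fact
there is no evidence at all. The same reasoning applies to a query typing
fewer markers than the search's `min_markers` floor.

## Database search

Each reference is scored against the query; results with
`score ≥ score_filter` (default 70%) and at least `min_markers` (default 8)
usable markers are retained, sorted by score descending with ties broken by
reference name ascending (equal scores have no published ordering rule;
lexicographic is reproducible). Exclusions are reported with reasons, not
dropped — an authentication audit needs the negative evidence. Filtering is
monotone in the threshold by construction.

### The DC2.4 discrepancy

From the packaged table's printed alleles, DC2.4 scores 75.00%
(shared 15: markers 1-1, 2-1, 4-2 and 17-2 share nothing and 7-1 shares
two; totals 20 + 20). The score on record for the original database search
is 78.05%, which cannot be derived from any set-semantics reading of the
printed alleles; the live database entry at search time evidently differed
from the table snapshot. The package reports the computed 75.00 and treats
only the other six neighbours (AT-3 82.93, YUMMER1.7-H2B-GFP5 80.00, MS1
78.05, YUMM1.7 76.92, MCA-205 76.19, MLTC-1 73.17) as regression anchors.

## Allele calling

Peak tables arrive as `(marker, allele, height)` triples — fragment sizing
and repeat binning happen upstream in the instrument software, so alleles
are pre-binned. Per marker: duplicate allele entries merge keeping the
maximum height; alleles with height **≥** the detection threshold are
called (default 100 RFU; a peak exactly at the threshold passes — the
threshold is a pass level, not a strict bound); more than two survivors at
a diploid locus flags `multi_allelic`; no survivors flags `no_signal`.
Sub-threshold peaks are retained in the per-marker QC record but never
called. A single global threshold is used; whether commercial assays apply
marker-specific thresholds or stutter filters is not public, and no
stutter/pull-up modelling is attempted.

Calling is invariant to peak order, monotone in the threshold (raising it
never adds an allele), and exactly inverts the synthetic peak generator in
the noise-free case — all three are tested properties.

## Synthetic data

The generator exists because public mouse STR data are scarce: there are no
allele-frequency tables for the CellCheck panel loci. It emulates the
*structure* of real profiles, not their population genetics:

- **Profiles** (`generate_profile`): every marker typed, 1–2 alleles drawn
  uniformly over the whole repeats inside the marker's known allele range
  (a microvariant lower bound like `7.1` excludes its integral allele `7`).
  `het_prob` (default 0.5) sets the chance of a second draw; two equal
  draws collapse to homozygous, as in real typing. `microvariant_prob`
  (default 0.15) attaches a `.1`–`.3` microvariant when the result stays in
  range. Uniform sampling is a modelling convenience — real allele
  frequencies are highly skewed across inbred strains — so synthetic
  match-score distributions are *not* calibrated to real inter-line
  similarity; tests passing on synthetic data demonstrate algorithmic
  correctness, not biological realism. `het_prob` has no paper-derivable
  value; 0.5 is a plausible mid-range for lines of mixed inbred ancestry.
- **Drift** (`mutate_profile`): models the progressive divergence of
  continuous cultures as independent per-allele dropout (`dropout_rate`)
  and ±1-repeat shifts (`shift_rate`), clipped to the marker's known range
  (a shift that would leave the range is reflected; if both directions
  leave the range the allele is kept). Markers may drift to empty.
  `drop_alleles` provides the deterministic counterpart: removing exactly
  `k` of `n` alleles gives the closed-form Tanabe score
  `100·2(n−k)/(2n−k)` against the original (scored over the query's
  markers, since deletions may empty a marker entirely), which the tests
  verify for every `k < n` across the panel's achievable totals
  (19 ≤ n ≤ 38 for a 19-marker diploid panel).
- **Peak tables** (`generate_peak_table`): one peak per allele, heights
  log-uniform in `[2t, 100t]` for threshold `t = 100` RFU so noise-free
  calling is unambiguous while spanning the dynamic range of real
  electropherograms. An optional contaminant profile is mixed in with
  heights scaled by `contaminant_fraction`; a contaminant allele already
  present in the host adds to the host peak. No stutter, pull-up, or
  baseline noise is modelled.

All randomness flows through `numpy.random.default_rng` seeded from
`SimConfig.seed` (each operation salts the seed so profile, drift, and peak
draws are independent streams); equal configurations give bitwise-equal
outputs.

## Numerical and testing choices

- Score arithmetic is exact small-integer division in floating point; the
  brute-force cross-check in the test suite (literal per-marker set
  intersection over token strings, independent of the library path) must
  agree to machine precision, with no tolerance.
- Worked-example scores are asserted at the two decimals they are printed
  with; everything derived analytically (closed-form drift) at
  `rel_tol = 1e-12`.
- Problem sizes in the test suite — 200+ random profile pairs for oracle
  equivalence, 400 profiles for dropout-rate recovery, 100 seeds for the
  calling round trip — keep the whole suite around one second while giving
  the stochastic checks comfortable margins (the dropout check uses a
  3-standard-error band).

## Limitations

- Set-valued genotypes discard copy number: a true homozygote and a
  hemizygous deletion are indistinguishable, as in the underlying assay.
- No probabilistic match interpretation (likelihood ratios, allele
  frequencies) — percent match is a descriptive statistic only.
- The search operates on local CSV databases; it does not query online
  STR databases.
- No in-silico PCR or fragment-size prediction from the packaged primer
  sequences, and no interspecies-contamination caller.
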