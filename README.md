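# strauth — mouse STR profile authentication

Misidentification, cross-contamination and genetic drift of continuous cell
lines are persistent problems in biomedical research. The accepted remedy is
short tandem repeat (STR) profiling: genotype a panel of polymorphic
microsatellite loci and compare the resulting allele profile against
reference databases. `strauth` implements that workflow for mouse cell lines
over the 19-marker CellCheck panel:

- a domain model for STR alleles (including microvariants such as `20.3`),
  set-valued genotypes, and multi-locus profiles, with a compact CSV
  interchange format;
- the **Tanabe** percent-match statistic and both **Masters** variants;
- database search with the standard filter settings (Tanabe scoring over
  markers non-empty in both profiles, 70% score filter, minimum 8 usable
  markers);
- threshold-based allele calling from electropherogram peak tables
  (default 100 RFU), with QC flags for silent and multi-allelic loci;
- a synthetic-data generator for panel-conformant profiles, drifted
  variants, and mixture peak tables.

The package ships the reference profile of the Col-GFP HSC hepatic stellate
cell line (Cellosaurus `CVCL_B7MI`) and the published comparison of that
profile against its seven nearest neighbours in the Cellosaurus mouse STR
database, which serve as worked examples and regression anchors.

## The statistic

For a query profile $Q$ and reference profile $R$ compared over a marker set
$M$ (by default the markers typed in **both** profiles), with $Q_m$ and
$R_m$ the allele *sets* at marker $m$:

$$\text{Tanabe} = 100 \cdot \frac{2\sum_{m \in M} |Q_m \cap R_m|}{\sum_{m \in M} |Q_m| + \sum_{m \in M} |R_m|}$$

$$\text{Masters}_{\text{query}} = 100 \cdot \frac{\sum_m |Q_m \cap R_m|}{\sum_m |Q_m|}, \qquad \text{Masters}_{\text{ref}} = 100 \cdot \frac{\sum_m |Q_m \cap R_m|}{\sum_m |R_m|}$$

Genotypes are sets: a homozygous locus contributes one allele, a tri-allelic
(amplified) locus three. Microvariant alleles are distinct from their
integral neighbours (`27.2` matches neither `27` nor `26.2`). Scores are
reported rounded half-up to two decimals.

## Worked example

Materialize the packaged fixtures and search the Col-GFP HSC profile against
the seven-line reference table:

```sh
strauth fixtures --out fx
strauth search --query fx/colgfp_reference.csv --db fx/similarity_table.csv
```

prints the marker-by-line table and the score footer:

```
STR similarity search — query: Col-GFP HSC
algorithm=tanabe mode=non_empty_both score_filter=70% min_markers=8

marker   Col-GFP HSC  AT-3       YUMMER1.7-H2B-GFP5  MS1       YUMM1.7  MCA-205  DC2.4      MLTC-1
1-1      16           16         16,17               17        16,17    16       17         16
...
X-1      27           27         27                  27        27       27       27         28
% match               82.93      80.00               78.05     76.92    76.19    75.00      73.17
```

The top hit, AT-3 at 82.93%, sits well below the ~90% threshold
conventionally taken to indicate a shared origin: the Col-GFP HSC profile is
unique among the database lines while remaining plausibly mouse (every
neighbour clears the 70% filter on this inbred-species panel, where many
loci share common alleles). A single pair can be scored directly:

```sh
strauth score --query fx/similarity_table.csv --reference fx/similarity_table.csv --reference-name AT-3
# Col-GFP HSC vs AT-3: 82.93% (17 shared / 20+21 alleles, 18 markers, tanabe)
```

i.e. 17 shared alleles against totals of 20 (query) and 21 (reference) over
the 18 markers typed in both profiles: 100·2·17/41 = 82.93%.

Note on DC2.4: its score recomputes to 75.00% from the alleles in the
packaged table, not the 78.05% on record for the original database search;
the live database entry evidently differed from the published table
snapshot. See `docs/methods.md`.

Allele calling and simulation:

```sh
strauth simulate peaks --seed 7 --out peaks.csv     # synthetic electropherogram summary
strauth call --peaks peaks.csv --rfu 100 --name demo
```

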