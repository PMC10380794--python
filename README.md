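# phyprof

Phyletic profiling of the C1A (papain-family) cysteine-peptidase gene
families: sequence-to-family classification, presence/absence matrices,
ancestral gene-content reconstruction, desk-scale gene trees, and
horizontal-gene-transfer detection with independent-event counting.

The package ships literal transcriptions of the published
presence/absence survey tables (eukaryote supergroups, the Obazoa
detail, and the prokaryote backbone) together with reference trees that
encode the tables' nested row structure. On top of those fixtures it
reimplements the inference chain behind the headline result — eight
ancestral paralogous C1A lineages (cathepsins B, C, X, L, F, H, the
26/29 kDa peptidase, and the type 1 long C1 peptidase) present in the
last eukaryotic common ancestor, with a single undifferentiated C1A
ancestor at FECA and LUCA.

## Modules

| module | what it does |
| --- | --- |
| `phyprof.taxa` | rooted reference trees, Newick I/O, MRCA/clade queries, rerooting |
| `phyprof.profiles` | taxa x family presence/absence/unknown matrices, TSV I/O, merging |
| `phyprof.classify` | PSSM family profiles, glocal DP scoring, E-value acceptance, catalytic-triad and propeptide checks |
| `phyprof.ancrec` | Dollo parsimony and two-state ML gain/loss reconstruction with branch-mapped events |
| `phyprof.genetree` | Poisson-corrected distances, neighbor joining, nonparametric bootstrap |
| `phyprof.hgt` | identity-differential (alien-index-style) transfer flagging, donor assignment, event clustering |
| `phyprof.simulate` | synthetic content/sequence generator with recorded ground truth; named benchmark regimes |
| `phyprof.report` | pipeline orchestration, manifests, rendered ancestral-state tables |

Design notes worth knowing:

* Database homology searches are replaced by self-contained profile
  scoring; the E ≤ 1e-5 acceptance threshold is retained, and ties
  within 5 bits of the runner-up family are reported `unclassified`
  rather than guessed.
* Full ML tree inference (WAG+I+G4) is deliberately out of scope;
  neighbor joining over Poisson-corrected distances is the desk-scale
  stand-in, used only for monophyly checks and transfer-donor
  placement.
* Matrix rows may name internal tree nodes (the printed tables score
  whole clades such as Obazoa); reconstruction treats these as
  ancestral-state observations.
* The transfer threshold (anomaly score ≥ 0.10) is explicit
  configuration — the underlying criterion ("unusually high conservation
  between distant organisms") is qualitative.

## CLI

Everything is reachable through the `profiler` umbrella command:

```sh
profiler tree validate src/phyprof/data/eukaryota.nwk
profiler matrix merge t1.tsv t2.tsv -o merged.tsv
profiler ancrec --method dollo --matrix fixtures:eukaryote --tree fixtures:eukaryota -o out/
profiler classify --fasta seqs.fasta --e-cutoff 1e-5 -o out/
profiler genetree --aln aln.fasta --bootstrap 1000 --seed 1
profiler hgt --fasta seqs.fasta --clades clades.tsv --taxa-map ids.tsv \
    --focal-clade Metazoa --focal-clade Fungi -o out/
profiler simulate --fixture five_hgt_cases --out fixtures/
profiler run --config pipeline.json -o out/
```

`--matrix`/`--tree` accept file paths or `fixtures:<name>` for the
packaged data (`table1`…`table6`, `eukaryota`, `prokaryota`,
`combined`). `profiler run` drives the staged pipeline
(classify → matrix → ancrec → genetree → hgt → tables) from a single
JSON config and writes a manifest with per-stage timings and output
hashes.

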