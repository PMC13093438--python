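# phyloconflict

Toolkit for dissecting gene-tree/species-tree discordance in phylogenomic
datasets: single-copy-ortholog filtering, PhyParts-style concordance
accounting, multispecies-coalescent (MSC) simulation, attribution of
cyto-nuclear conflicts to incomplete lineage sorting, and invariants-based
hybridization detection with inheritance-probability (γ) estimation and a
null-simulation false-positive filter. A synthetic-data module generates
complete test scenarios (species trees, reticulations, MSC gene trees,
GTR+Γ alignments, occupancy tables) so every stage runs without external
data or binaries.

## Package layout

| module | contents |
|---|---|
| `phyloconflict.trees` | Newick I/O, bipartition algebra, Robinson–Foulds distance, support handling, outgroup rooting |
| `phyloconflict.alignment` | alignment container, FASTA / relaxed-PHYLIP I/O |
| `phyloconflict.nj` | tool-free NJ + bootstrap gene-tree fallback (Jukes–Cantor) |
| `phyloconflict.simulate` | MSC and network-MSC gene-tree simulation, GTR+Γ sequence evolution, missingness injection |
| `phyloconflict.scenarios` | `adonis_like` / `no_hybrid` / `rate_artifact` scenario bundles |
| `phyloconflict.filters` | occupancy, organellar k-mer screen, column trimming, length classes, ABS filter, long-branch flagging, supermatrix concatenation |
| `phyloconflict.concordance` | per-node concordance/conflict pies, cloud-tree preparation |
| `phyloconflict.ils` | RF-distance distributions vs the MSC null, conflict attribution to ILS |
| `phyloconflict.hyde` | quartet site-pattern counting, invariants z-test and γ estimation, all-triples scan, Node-Mode MRCA aggregation, null-simulation filter |
| `phyloconflict.pipeline` / `cli` / `report` | end-to-end runner, subcommand CLI, SVG reports |

The statistic implemented in `phyloconflict.hyde` is derived in
`docs/hils_statistic.md` and validated by calibration and recovery
simulations in the test suite.

## CLI

```bash
# generate a synthetic bundle with one reticulation (gamma = 0.6)
phyloconflict simulate adonis_like --seed 1 --out bundle/

# run the full pipeline (filter -> concordance -> ILS -> hybridization
# scan -> null filter -> reports)
phyloconflict run --bundle bundle/ --out results/ --seed 1 --config cfg.json
```

`cfg.json` overrides any `AnalysisConfig` field, e.g.
`{"length_classes": [1], "n_sim": 10000, "null_replicates": 20}`.
Partial stages are available as `filter`, `concord`, `ils`, `hyde`,
`nullfilter` and `report`. Exit codes: 0 success, 2 invalid config,
3 stage failure (a `failed/<stage>` marker is left in the output
directory).

Outputs are TSV tables plus Newick trees, SVG figures (species tree with
concordance pies, distance histogram, γ heatmap) and a `manifest.json`
recording the config, input checksums and produced files; reruns with the
same seed are byte-identical.

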