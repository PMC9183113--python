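# satscout

Satellite-DNA discovery and rDNA-linkage analysis for plant genomes.

`satscout` is built for the analysis pattern behind satellites like the
hemp (*Cannabis sativa*) repeat CS-237: a tandem repeat with a ~237 bp
monomer that is itself a higher-order repeat (HOR) of two diverged
subunits (111 and 126 bp), lives both in independent chromosomal arrays
and — as a shortened, reverse-oriented 208 bp variant (delCS-237) — in
pairs inside the intergenic spacer (IGS) of the 45S rDNA. The package
covers every desk-side step of characterizing such a repeat:

- **simrep** — a synthetic-genome generator that plants tandem arrays,
  45S rDNA units (18S–ITS1–5.8S–ITS2–26S–IGS) with embedded spacer
  copies, and writes a truth manifest (JSON/GFF3/BED) for scoring.
- **aligncore** — affine-gap global alignment, percent identity
  (matches over all columns, end gaps trimmed), and a seed-and-extend
  local search producing HSPs on both strands, with two stringency
  presets (`relaxed`: ≥85 % identity, ≥95 % query coverage; `strict`:
  ≥90 % identity).
- **tandemscan** — de novo period detection from k-mer recurrence
  distances, monomer segmentation by prefix alignment, column-majority
  consensus building, and HSP chaining into arrays with fractional
  copy numbers (an array of "about 2.5 monomers" is reported as 2.5).
- **horstruct** — subunit decomposition of a monomer by scoring every
  split point for inter-half similarity, cross-family subunit
  alignment with indel calls (e.g. the single 27 bp deletion that
  separates a derived family from its progenitor), and strand-aware
  family classification.
- **rdnalink** — rDNA unit annotation, IGS delineation (26S 3′ end to
  the next 18S 5′ end), independent-vs-IGS-linked copy classification,
  per-spacer copy-multiplicity histograms, N/P spacer-configuration
  calls (co-oriented vs inverted flanking units), and deletion
  inference between IGS length variants.
- **profilemap** — binned HSP coverage profiles, merged array regions,
  genome-fraction estimates per stringency preset, and in-silico PCR
  amplicon-ladder prediction.
- **pipeline / cli** — a `satscout` command with subcommands
  `simulate`, `scan`, `decompose`, `rdna`, `profile`, `pcr`, `report`.

## Worked example

Simulate the bundled demo genome (an independent array on `chrA`; an
array plus a six-unit rDNA cluster with paired spacer copies on
`chrB`), then scan it:

```sh
satscout simulate --out demo/sim --seed 1
python - <<'EOF'
import json
man = json.load(open("demo/sim/manifest.json"))
monos = [r for r in man["records"] if r["kind"] == "monomer_refs"][0]["sequences"]
open("demo/monomers.fa", "w").write(
    "".join(f">{k}\n{v}\n" for k, v in monos.items()))
EOF
satscout scan --genome demo/sim/genome.fa --monomers demo/monomers.fa --out demo/scan
satscout report --run-dir demo/scan
```

The run report's stage summary reads (abridged):

```
{'stage': 'local_search', 'hsps_CS237like': 32, 'hsps_delCS237like': 12}
{'stage': 'delineate_arrays[CS237like]', 'arrays': 2}
{'stage': 'decompose[CS237like]', 'subunits': 2, 'consensus_length': 237}
{'stage': 'rdna', 'units': 6, 'igs': 5, 'igs_linked': 10, 'independent': 34,
 'multiplicity_mode': 2, 'multiplicity_histogram': {2: 5},
 'n_config': 5, 'p_config': 0}
```

Reading: the 237 bp family is found as 32 HSPs forming the two planted
arrays, and its consensus decomposes into two subunits. All six rDNA
units are recovered; the five complete spacers each carry exactly two
embedded copies of the derived family (multiplicity mode 2), all
spacers are N-configuration (co-oriented flanks), and the independent
array copies stay classified independent.

In-silico PCR on a clean ten-copy array with one primer pair anchored
inside the monomer prints a ladder whose step equals the monomer
length, e.g. `lengths [190, 427, 664, ...]`, `step 237` — the
ladder-like gel pattern characteristic of tandem arrays.

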