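# crypticnes

Discovery and quantification of **cryptic nuclear export signals**
(NES): leucine-rich CRM1-recognition motifs that are buried in a
protein's native fold and become export-competent only when misfolding
exposes them. The package was built around the canonical case — human
SOD1, whose ALS-linked mutants are cleared from the nucleus via a
normally buried NES-like sequence — and is aimed at structural
bioinformaticians and cell biologists who want to scan candidate
proteins, score anchor burial, and quantify the downstream imaging and
organismal readouts with reproducible code.

## What it computes

1. **Consensus scanning** (`crypticnes.motifs`). An NES class is an
   anchor/spacer pattern Φ⁰-X<sub>a</sub>-Φ¹-X<sub>b</sub>-… with
   hydrophobic anchors Φ ∈ {L, I, V, F, M}. The default PKI class is
   Φ⁰-X₂-Φ¹-X₃-Φ²-X₂₋₃-Φ³-X-Φ⁴. Scanning enumerates every placement
   exhaustively; overlapping placements merge into candidate regions.
2. **Burial analysis** (`crypticnes.structure`). Shrake–Rupley SASA
   with a deterministic 960-point golden-spiral quadrature; relative
   solvent accessibility RSA = SASA / maxASA (Gly-X-Gly reference);
   residues with RSA ≥ 0.20 are exposed.
3. **Cryptic calling** (`crypticnes.cryptic`). A match with ≥ 4 of 5
   anchors buried is *cryptic*; ≤ 1 buried is *surface*; otherwise
   *ambiguous*.
4. **Imaging quantification** (`crypticnes.imaging`). Per-cell
   nuclear/total (N/T) fluorescence ratios from two-channel images;
   group time courses normalized to the t = 0 mean.
5. **Phenotype statistics** (`crypticnes.stats`). Bagging rates, egg
   counts, body-bend rates, uncensored survival curves, relative IP
   efficiency, and paired/unpaired two-tailed Student's t-tests.
6. **Synthetic data** (`crypticnes.synthetic`). Generators with known
   ground truth for every input class: planted-motif peptides, toy
   structures with closed-form SASA, two-compartment cell images with
   known N/T, and per-animal phenotype tables.

## Worked example

```python
from crypticnes import scan_nes, apply_mutations, parse_mutation_code
from crypticnes.motifs import PKI_CLASS, RELAXED_CLASS, merge_matches
from crypticnes.reference import nlp_peptide, sod1_mature

nlp = nlp_peptide()            # residues 33-51 of mature SOD1
(match,) = scan_nes(nlp, PKI_CLASS)
print(match.anchors)           # (35, 38, 42, 45, 47)
print(match.matched_subsequence(nlp))  # IKGLTEGLHGFHV

mutant = apply_mutations(nlp, [parse_mutation_code("L42Q")])
print(len(scan_nes(mutant, PKI_CLASS)))  # 0

regions = merge_matches(scan_nes(sod1_mature(), RELAXED_CLASS))
print([r.span for r in regions])  # [(29, 50), (94, 106)]
```

The single PKI-class match on the 33–51 peptide places its five anchors
at I35, L38, L42, F45 and V47 — exactly the five residues whose
substitution by arginine abolishes nuclear export of mutant SOD1 — and
the L42Q substitution (the residue mouse SOD1 carries naturally)
destroys the consensus, printing zero matches. The relaxed discovery
scan of the full mature sequence nominates two candidate regions; only
the first, containing the 35–47 consensus, is functional.

From the shell:

```bash
crypticnes scan --fasta sod1.fasta --class pki
crypticnes sasa --pdb 2c9v.pdb --chain A --threshold 0.20
crypticnes call --fasta sod1.fasta --pdb 2c9v.pdb --chain A
crypticnes simulate images --seed 1 --cells 30 --fraction 0.5 --out sim/
crypticnes quantify --signal sim/signal.tif --nuclei sim/nuclei.tif
```

## Layout

```
src/crypticnes/
  sequences.py   sequences, mutations, FASTA I/O
  motifs.py      consensus classes, scanning, regions, conservation
  structure.py   PDB parsing, Shrake-Rupley SASA, RSA, exposure
  cryptic.py     cryptic/surface calling and reports
  imaging.py     segmentation, N/T measurement, time courses
  stats.py       phenotype and densitometry statistics
  synthetic.py   ground-truth generators
  cli.py         command-line interface
```
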