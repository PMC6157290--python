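# sgmfilter

Spectrum-graph-matching (SGM) protein sequence filtration for top-down
tandem mass spectrometry.

## The problem

In top-down proteomics an intact proteoform is fragmented and the
deconvoluted MS/MS spectrum — a precursor (molecular) mass plus a list of
neutral monoisotopic fragment masses — must be matched to a protein in a
sequence database. When the proteoform carries post-translational
modifications or mutations, aligning every spectrum against every database
sequence is far too slow, so a *filter* first reduces the database to a
handful of candidates per spectrum. Classic filters extract sequence tags or
gapped tags from the spectrum and search those; they lose sensitivity when
they must decide up front which peaks are signal. `sgmfilter` skips tag
selection entirely: it searches the *whole spectrum graph* — every gapped
tag it contains, noise paths included — against the database in one pass.

## The method

1. **Discretization.** Residue masses are multiplied by a scale factor
   (default 100) and rounded, giving an integer alphabet Σ of 19 symbols
   (Leu/Ile collide). A protein becomes a *text string* of integers; all
   database proteins are concatenated with unique separators and indexed by
   a suffix tree (Ukkonen's construction).
2. **Subspectra.** Up to γ fragment-dense mass intervals of width δ are
   chosen greedily (overlap controlled by ρ, at least 6 masses each), after
   a windowed intensity-rank noise filter (top-λ within ±100 Da). Each
   interval is also mirrored through the precursor mass M (`b → M − b`) so
   suffix-fragment ladders become readable in N-to-C order.
3. **Spectrum graphs.** Nodes are the interval's masses; an edge joins two
   nodes when their mass difference is ≤ α and is the total mass of at least
   one amino-acid string (checked in a precomputed composition table C(e),
   tolerance ε). Each node keeps its d = 3 smallest-label out-edges. Every
   path spells a *blocked pattern* of mass gaps.
4. **Search.** For each graph the restricted search propagates, node by
   node, the set B_i of suffix-tree positions of *identifiable* prefix text
   strings — candidate spellings that actually occur in the database. An
   edge labeled e extends each position along every residue string of mass
   ≈ e that survives in the tree. Matches are reported for paths running
   from within β Da of the lightest node to within β Da of the heaviest.
5. **Ranking.** A protein's similarity score is the best path score of any
   match (node count under the default mass-count scheme). The *extended*
   similarity score then shifts the protein's whole theoretical fragment
   ladder by the match-derived mass offset and counts aligned experimental
   masses — this is the default ranking score. The top-K (20) proteins per
   spectrum are reported; *filtration efficiency* is the fraction of spectra
   whose true protein survives into the top K.

The worst-case growth of the candidate spellings per gap is governed by the
expansion factor `r = max |C(e, j)|^(1/j)` (about 2.91 for gaps up to
350 Da at scale 100), which with the out-degree cap keeps the average search
cost sublinear in the database size.

## Worked example

No external data is needed — the package generates its own fixtures:

```bash
sgmfilter fixtures --n-proteins 20 --n-spectra 5 --miss-prob 0.2 \
    --n-noise 4 --seed 7 --out fix
sgmfilter run --db fix/proteins.fasta --spectra fix/spectra.msalign \
    --gamma 5 --out results.tsv
sgmfilter eval --results results.tsv --truth fix/truth.tsv --top 20
```

which prints

```
wrote fix/proteins.fasta, fix/spectra.msalign, fix/truth.tsv
wrote rankings for 5 spectra to results.tsv
filtration efficiency at top-20: 1.0000 (5/5 spectra)
```

and the first lines of `results.tsv` are

```
spectrum_id  rank  protein_id  similarity_score  extended_score  matched_substring  offset  orientation
S0000        1     P0008       8.0               62.0            NCHSSNVG           25      forward
S0000        2     P0007       4.0               4.0             VACNH              3       reversed
```

Spectrum `S0000` was generated from protein `P0008` with 20% of its ladder
missing and 4 noise masses: an 8-node path (similarity 8) spelled the
substring `NCHSSNVG` at offset 25, and after the ladder shift 62 of the
spectrum's fragment masses aligned (extended score 62), putting the true
protein at rank 1 well clear of the chance-level candidates below it.

The same pipeline is available as a library:

```python
from sgmfilter import (ResidueAlphabet, build_composition_table,
                       ProteinIndex, SGMParams, filter_database)

alphabet = ResidueAlphabet(scale=100)
table = build_composition_table(alphabet, max_mass=35002, tol=2)
index = ProteinIndex.build("fix/proteins.fasta", alphabet)
ranking = filter_database(spectrum, index, table, SGMParams())
```

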