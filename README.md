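# longlem

Long **locally maximal exact matches** (LEMs) between a query pattern and a
run-length-compressed text index.

## The problem

Pangenome and biobank-scale haplotype collections are enormous but extremely
repetitive, so they are indexed in *BWT-runs compressed* form: the
Burrows–Wheeler transform of a collection of near-identical sequences has
r ≪ n maximal equal-character runs, and modern indexes (the r-index and its
move-data-structure successors) answer pattern queries in O(r) words of
space.

Classic match reporting on such indexes finds **MEMs** — matches that cannot
be extended *in the pattern*. MEMs miss biologically informative matches: a
haplotype that is similar, but nowhere maximally similar, to the query
contributes no MEM at all. A **LEM** is a match P[i, j] = T[i′, j′] that
cannot be extended *simultaneously* in pattern and text:

    (i = 1  or  i′ = 1  or  P[i−1] ≠ T[i′−1])   and
    (j = m  or  j′ = n  or  P[j+1] ≠ T[j′+1])

Every MEM is a LEM; a *long LEM* is a LEM of length ≥ ℒ. This package
implements

* a compressed index (`MoveIndex`) of three balanced **move data
  structures** — over LF, φ and φ⁻¹ — augmented with per-interval PLCP
  samples so that φ(i), φ⁻¹(i), PLCP[i] and PLCP[φ⁻¹(i)] are all answered in
  constant time in O(r) words; and
* a long-LEM query that, given the matching statistics of P, reports **all**
  long LEMs in O(m + occ) expected operations, where m = |P| and occ is the
  output size — plus an O(mℒ + occ) variant that needs no matching
  statistics.

The algorithm sweeps a length-ℒ window right-to-left across the pattern,
maintaining the *balanced sa_lcp-interval* of the window (the suffix-array
interval [b, e] with a middle row d, their SA values, and the six
move-structure interval indices that make every step O(1)) and a
diagonal-keyed dictionary of live text suffixes. Per step it (1) emits every
live suffix whose preceding text symbol differs from the next pattern symbol
(its match just became left-maximal), (2) left-extends the interval by that
symbol through the LF move structure, and (3) re-admits, via constant-time
PLCP queries, exactly the suffixes whose common prefix with the remaining
pattern is ℒ (their matches are right-maximal there).

## Worked example

Command line — simulate a small panel of four near-identical haplotypes,
index it, and query the held-out fifth haplotype:

```sh
longlem simulate --haplotypes 4 --length 60 --rate 0.03 --seed 11 \
                 --out panel.fa --query query.fa
longlem build --input panel.fa --output index.json
longlem longlem --index index.json --pattern query.fa --min-length 20 \
                --out matches.tsv
```

which logs

```
longlem: simulated 4 haplotypes of length 60 (rate 0.03)
longlem: built index: n=244 r=93 intervals(LF/phi/phi_inv)=98/110/111 d=2
longlem: reported 3 matches
```

and writes (1-based inclusive coordinates, resolved per sequence):

```
pattern_id  p_start  t_seq_id  t_offset  length
query       1        hap2      1         51
query       7        hap3      7         29
query       37       hap3      37        24
```

The query shares a 51-symbol prefix with haplotype 2; haplotype 3 matches it
only in two shorter stretches that a MEM reporter would overshadow. Verify
against the brute-force enumerator with
`longlem oracle --text panel.fa --pattern query.fa --min-length 20` — the
TSVs are identical.

The same from Python, on the six-symbol fixture text:

```python
>>> import longlem as ll
>>> text = ll.Text.from_strings(["ABAAB"])          # indexed as ABAAB$
>>> idx = ll.build_index(text)
>>> structs = ll.SuffixStructures.from_text(text)
>>> P = text.encode_pattern("AAB")
>>> ms = ll.augment_ms(idx, ll.compute_ms_oracle(structs, P))
>>> sorted(ll.long_lem_query(idx, P, ms, 2))
[LemTriple(p_start=1, t_start=3, length=3), LemTriple(p_start=2, t_start=1, length=2)]
```

`AAB` matches T[3,5] over its full length, and its suffix `AB` matches
T[1,2] (left-blocked by the text edge). The occurrence of `AB` at T[4,5] is
*not* a LEM: it extends simultaneously to the full `AAB` match.

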