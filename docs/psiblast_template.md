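# Recommended homology-search command

`profclust` consumes tabular search output; it does not run the search.
The filters assume full sequence lengths (`qlen`/`slen`), not alignment
lengths, and an E-value cutoff of 10⁻³ applied at profile construction.

For a profile study over a large protein database, run three PSI-BLAST
iterations per query and keep the final-round table:

```sh
psiblast -query proteome.fasta -db refseq_protein \
    -num_iterations 3 -evalue 0.001 \
    -outfmt "6 qseqid sseqid evalue qlen slen staxids" \
    -out hits.tsv
```

Notes:

* `-evalue 0.001` bounds reported hits; `profclust` re-applies the same
  threshold, so a looser search cutoff is also fine.
* If your BLAST database lacks taxonomy ids (`staxids` prints `N/A`), drop
  the column and supply a two-column accession→taxid mapping file instead
  (`profclust.blast_io.load_taxid_map` / `attach_taxids`).
* With PSI-BLAST, only the last iteration's rows should be kept (the
  table repeats per round; take the block after the final
  `Search has CONVERGED!` or the last `# Iteration:` marker).
* The 80–120% subject-length window and the exclusion of the query
  organism's own species are applied by `profclust.blast_io.filter_hits`
  and the species-mapping step, not by the search.
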