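# Data directory

No third-party data ships with this repository.  The full Alzheimer's-disease
causal loop diagram (38 variables, 150 connections) is deposited as a
supplementary workbook alongside the article it comes from and must be
transcribed here once to enable the full-diagram checks:

* `ad_cld_variables.csv` — header `name,category,scale,definition`
  (category one of `brain`, `physical`, `psychosocial`; scale/definition
  optional).
* `ad_cld_edges.csv` — header `source,target,polarity,evidence`
  (polarity `+`/`-`/`+1`/`-1`; evidence optional, `;`-separated).

If the workbook uses different column headers or sheet layout, load it with
`cldnet.read_workbook(path, column_map=...)` and re-export with
`cldnet export` instead of editing by hand.

Everything else the tests need (the printed-loop-table fixture, random and
planted synthetic diagrams) is generated programmatically by
`cldnet.synthetic`.
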