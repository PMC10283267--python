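# File formats

## Metadata CSV

UTF-8, comma-separated, RFC-4180 quoting, first row header. Grammar
(EBNF; `csv-field` is an RFC-4180 field):

```
metadata   = header NL { row NL } ;
header     = "name,type,min,max,legend" ;
row        = name "," type "," [ int ] "," [ int ] "," [ legend ] ;
name       = csv-field ;                      (* unique per document *)
type       = "binary" | "categorical" | "integer_bounded"
           | "integer_unbounded" | "continuous" | "toothlist" ;
legend     = pair { ";" pair } ;
pair       = int "=" label ;
int        = [ "-" ] digit { digit } ;
label      = { character - (";" | ",") } ;
```

Constraints: `min`/`max` are required for `categorical` and
`integer_bounded` (and fixed to 0/1 for `binary`, where they may be
omitted); `toothlist` and the unbounded kinds take no range; every
legend key must lie in the variable's domain.

## Dataset CSV

UTF-8, comma separator, header row naming columns declared in the
metadata. Scalar cells are decimal literals; tooth-list cells are
two-digit FDI codes joined by `;`. The empty string is the empty set
for tooth-lists and missing for scalar kinds; the missing sentinel
(default `NA`) is missing for every kind.

## Report JSON

One document with required sections `report_version`, `task`,
`roster_metrics`, `best_model`, `explanations`, plus optional `search`
and `decision_tree`. `explanations` must carry `base_value`,
`parent_names`, `parent_values` and `global_importance`; when `search`
is present its `trace` length must equal `evaluations_performed`.
`clinselect.validate_report` enforces this structure.

## Model bundle

A zip archive: `meta.json` (format version, roster version, schema,
transform plan, task config, winning classifier spec, class labels)
plus `model.joblib` (the fitted model and the encoded background rows
used for explanations).
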