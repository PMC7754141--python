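# JSON model dialect

`fibroflux` reads and writes stoichiometric models in the community
constraint-based JSON schema, so files interoperate with other
constraint-based toolkits (cobrapy loads them directly).

Top-level object:

| key              | type   | meaning                                        |
|------------------|--------|------------------------------------------------|
| `id`             | string | model identifier                               |
| `version`        | string | schema version, `"1"`                          |
| `objective_sense`| string | `"max"` or `"min"`                             |
| `compartments`   | object | compartment code → name                        |
| `metabolites`    | array  | see below                                      |
| `reactions`      | array  | see below                                      |
| `genes`          | array  | `{ "id": ..., "name": ... }`                   |

Metabolite entry: `{"id": "phyt_c", "name": "", "compartment": "c"}`.
Metabolite ids are compartment-suffixed (`_e` extracellular, `_c` cytosol,
`_x` peroxisome, ...), and the suffix must agree with the `compartment`
field.

Reaction entry:

```json
{
 "id": "EX_phyt(e)",
 "name": "",
 "metabolites": {"phyt_e": -1.0},
 "lower_bound": -1000.0,
 "upper_bound": 1000.0,
 "gene_reaction_rule": "",
 "subsystem": "",
 "objective_coefficient": 0.0
}
```

Conventions and invariants enforced on load:

* negative stoichiometric coefficients are consumed, positive produced;
* bounds are in mmol·gDW⁻¹·h⁻¹ with `lower_bound ≤ upper_bound`; the
  defaults when omitted are ±1000 (reversible) and 0/1000 (irreversible);
* an exchange reaction has exactly one metabolite at coefficient −1, so
  flux < 0 is uptake and flux > 0 is secretion, globally;
* `gene_reaction_rule` is a boolean `and`/`or` expression over gene ids;
  the empty string means "not gene-associated" (always available);
* every metabolite cited by a reaction must be declared, and every gene
  cited by a rule must appear in `genes` (a missing `genes` array is
  reconstructed from the rules);
* a non-zero `objective_coefficient` marks the objective reaction.

Writing is byte-stable: serialising the same in-memory model twice (or a
read-back copy) produces identical files, with sorted keys and sorted
stoichiometry maps.

SBML import/export uses Level 3 + FBC v2 (flux bounds as shared
parameters, GPRs as gene-product associations); Recon-style ids containing
parentheses are escaped with the COBRA `_LPAREN_`/`_RPAREN_` convention
inside SBML identifiers and restored on read.

Tabular side formats:

* medium TSV: columns `reaction_id`, `lb`, `ub`;
* curation-edit TSV: columns `action` (`add_reaction`, `delete_reaction`,
  `add_metabolite`, `set_bounds`), `id`, `payload_json`;
* counts TSV: `gene_id` index column plus one integer column per sample;
* evidence TSV: columns `gene_id`, `evidence` ∈ {0, 1};
* measured-rates TSV: columns `reaction_id`, `group`, `rate`.
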