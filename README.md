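# morphotax

A descriptive-taxonomy toolkit for coded morphological character matrices:
natural-language taxon descriptions, minimal diagnoses, dichotomous key
generation, interactive multi-entry identification, and readers/writers for
canonical JSON, a documented DELTA dialect, and NEXUS.

The package ships a fully transcribed reference dataset: the Nereididae
genus matrix (45 genera × 186 characters — 146 unordered multistate plus 40
numeric/meristic), the published 49-couplet key to the genera encoded
verbatim (including its known couplet-18/19 cross-reference anomaly), and
the published per-genus minimal/secondary diagnosis character sets.

## Layout

| module                  | role |
|-------------------------|------|
| `morphotax.model`       | characters, attributes, taxa, datasets; comparison semantics (`differ`, `distinguishing_characters`, `validate_dataset`) |
| `morphotax.io`          | canonical JSON, DELTA dialect, NEXUS export/import |
| `morphotax.describe`    | natural-language descriptions |
| `morphotax.diagnose`    | minimal diagnoses at a DiagLevel (exact branch-and-bound or greedy) |
| `morphotax.keys`        | key generation, routing, rendering, consistency checks |
| `morphotax.identify`    | tolerance-based multi-entry identification |
| `morphotax.synthetic`   | seeded synthetic matrix generation |
| `morphotax.fixtures`    | the packaged Nereididae fixtures (checksummed JSON) |
| `morphotax.cli`         | the `morphotax` command |

## Comparison semantics

Two taxa *differ* on a character only when both cells are RECORDED and
their payloads are disjoint (state sets share no code; numeric intervals do
not overlap).  UNKNOWN and INAPPLICABLE never create a difference, so taxa
are never separated — and a specimen is never eliminated — on unscored
data.  All character numbers and state codes are 1-based.

Cells reconstructed as implicit values during fixture transcription carry
the comment `implicit`; cells curated against documented inconsistencies in
the source text carry a `curated: ...` comment.  Printed diagnoses that
cannot verify under the strict disjointness rule are listed, with reasons,
in the diagnoses fixture under `known_issues`.

## CLI

```sh
morphotax validate     --fixture nereididae-genera
morphotax describe     --fixture nereididae-genera --taxon Australonereis
morphotax diagnose     --fixture nereididae-genera --taxon Pseudonereis --level 1
morphotax key build    --fixture nereididae-genera --out key.json
morphotax key render   --key printed --fixture nereididae-genera
morphotax key route    --key printed --fixture nereididae-genera --taxon all
morphotax key check    --key key.json --fixture nereididae-genera
morphotax identify     --fixture nereididae-genera --specimen specimen.json
morphotax export-nexus --fixture nereididae-genera --out nereid.nex
morphotax convert      --fixture nereididae-genera --to delta --out nereid
morphotax fixtures     --export dumped/
morphotax synthesize   --taxa 8 --characters 12 --seed 7
```

A specimen file maps character numbers to observations, e.g.
`{"15": [1], "25": [2]}`.

Key generation defaults reproduce the reference settings RBASE=2.00,
ABASE=1.00 (reserved, inactive), REUSE=1.01, VARYWT=0.80, two confirmatory
characters; diagnosis defaults to DiagLevel=1.  The scoring formula is this
package's documented stand-in (normalized split entropy with reliability,
re-use, and variability weights); generated keys promise routing soundness
and completeness, not reproduction of the printed key text.

## Dataset JSON schema (version 1)

```json
{
  "format": "morphotax-dataset",
  "version": "1",
  "title": "...",
  "characters": [
    {"number": 1, "label": "...", "kind": "multistate|numeric",
     "states": ["..."], "unit": "...", "reliability": 5.0,
     "dependencies": [{"controller": 5, "states": [1]}], "section": "..."}
  ],
  "taxa": [
    {"name": "...", "authority": "...",
     "attributes": {"1": {"states": [1, 2], "comment": "..."},
                    "14": {"range": [2, 4]},
                    "7": {"status": "unknown"},
                    "6": {"status": "inapplicable"}},
     "metadata": {"type_species": "..."}}
  ]
}
```
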