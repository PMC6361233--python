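"""Parse a mutation-energetics table and summarize its composition.

Builds a small synthetic table in the SKEMPI 2.0 format, writes it to
disk, re-parses it with validation, and prints the composition summary:
how many entries there are, how many are unique mutation/complex
combinations, and how many carry kinetics, calorimetry or only an
affinity limit.
"""

import tempfile
from pathlib import Path

import skempi2 as sk
from skempi2.synthetic import GeneratorConfig, generate_table

entries, _ = generate_table(GeneratorConfig(seed=17, n_interactions=10))
path = Path(tempfile.mkdtemp()) / "example.csv"
sk.write_skempi_table(entries, path)
print(f"wrote {len(entries)} entries to {path}")

result = sk.parse_skempi_table(path)
print(f"re-parsed {len(result.entries)} entries, "
      f"{len(result.issues)} validation issues")

summary = sk.summarize_composition(result.entries)
for key, value in summary.items():
    if key != "per_method":
        print(f"  {key}: {value}")
# total counts every measurement row; unique collapses replicate
# measurements of the same mutation on the same complex; the qualified
# count is entries where only an affinity limit (>, <, no binding) exists
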