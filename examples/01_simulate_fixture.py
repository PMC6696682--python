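"""Simulate a complete benchmarking fixture: panel, truth and test VCFs.

Writes a multi-sample phased panel VCF, a sample->group table, and per
individual a phased truth VCF (with PS phase sets) plus a corrupted test
VCF with known genotype-error, switch-error and dropout rates recorded in
manifest.json.
"""

import json
from pathlib import Path

from haplobench import make_fixture_suite

out = Path("scratch_fixture")
manifest = make_fixture_suite(out, scale="small", seed=1)

print(f"fixture written to {out}/")
print(f"panel: {manifest['simulation']['n_haplotypes']} haplotypes "
      f"x {manifest['simulation']['n_sites']} sites")
print("injected corruption:", json.dumps(manifest["corruption"], indent=2))
for ind in manifest["individuals"]:
    print(f"  {ind['sample']}: {ind['n_truth_sites']} truth variants "
          f"({ind['truth_vcf']}, {ind['test_vcf']})")
# The manifest rates are what the concordance metrics should recover when
# run on these files -- see the other examples.
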