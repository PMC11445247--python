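"""Round-trip a simulated sample through a VCF, as a real workflow would.

Exports synthetic allelic depths as a single-sample VCF with AD fields,
re-reads it through the variant ingestion path with the standard site
filters (total depth 20-200, each allele > 7 reads), and calls ploidy on
the retained fractions.
"""

import tempfile
from pathlib import Path

from abploidy import (
    FilterConfig,
    SimConfig,
    call_ploidy,
    profile_from_sites,
    read_depths_from_variants,
    simulate_sites,
    write_vcf,
)

cfg = SimConfig(m=3, n_sites=2500, depth_min=25, depth_max=60, seed=7)
with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "sample.vcf"
    write_vcf(simulate_sites(cfg), vcf, sample_id="S1")
    sites = list(read_depths_from_variants(vcf, "S1", FilterConfig()))
    profile = profile_from_sites("S1", sites)
    call = call_ploidy(profile)

print(f"retained {profile.n_sites} of {cfg.n_sites} simulated sites")
print(f"call: {call.reported_ploidy} ({call.confidence_flag}); "
      f"true cytotype was {2 * cfg.m}x")
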