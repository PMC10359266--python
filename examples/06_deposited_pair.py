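"""Compare the deposited K⁺- and Na⁺-selective channelrhodopsin models.

Downloads PDB entries 8GI8 (HcKCR1, K⁺-selective) and 8GI9 (HcCCR,
Na⁺-selective) — requires network access — and runs the full comparison
with the literature defaults: 4.0/3.5 Å H-bond cutoffs, 0.5 Å grid,
1.4 Å surface probe, 0.9 Å tunnel probe, and the key residue pairs
Asp116–Arg244, Ser73–Asp116, Tyr106–His225, Tyr222–Trp102 and
Tyr222–Gln218.

Run:  python examples/06_deposited_pair.py [workdir]
"""

import sys
import urllib.request
from pathlib import Path

from poregraph import CompareConfig, run_compare

workdir = Path(sys.argv[1] if len(sys.argv) > 1 else "scratch")
workdir.mkdir(parents=True, exist_ok=True)

for code in ("8GI8", "8GI9"):
    dest = workdir / f"{code.lower()}.cif"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{code}.cif"
        print(f"fetching {url}")
        urllib.request.urlretrieve(url, dest)

report = run_compare(workdir / "8gi8.cif", workdir / "8gi9.cif", CompareConfig())
print(report.to_markdown())
(workdir / "report.json").write_text(report.to_json())
print(f"full JSON written to {workdir / 'report.json'}")
# Expected headline numbers from the deposited pair: H-bond graph totals
# 66 (24 water-mediated) vs 50 (17), Cα RMSD ≈ 0.45 Å, a ≈1.4 Å Val66
# Cα displacement, and an extracellular tunnel found only for the
# Na⁺-selective structure at the 0.9 Å probe.
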