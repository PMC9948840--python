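"""Regenerate the bundled elemental mass-attenuation fixture from scratch.

Usage: python scripts/generate_element_table.py [out.tsv]
"""
import sys
from pathlib import Path

from deqct import xs

out = Path(sys.argv[1]) if len(sys.argv) > 1 else (
    Path(__file__).resolve().parent.parent / "src/deqct/data/elemental_mu_rho.tsv"
)
table = xs.generate_table()
table["A"] = table["A"].map(lambda a: f"{a:.4f}")
table["mu_over_rho_cm2_g"] = table["mu_over_rho_cm2_g"].map(lambda v: f"{v:.6g}")
table["energy_keV"] = table["energy_keV"].map(lambda e: f"{e:g}")
table.to_csv(out, sep="\t", index=False)
print(f"wrote {out} ({out.stat().st_size} bytes, {len(table)} rows)")
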