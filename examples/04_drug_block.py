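"""Pharmacological conductance block: 10 uM moxifloxacin on TP06.

Each affected current is scaled by 1 / (1 + C/IC50) (Hill coefficient 1):
IC50 29 uM for I_Kr, 206.7 uM for I_Na, and 158 uM (pIC50 3.8) for I_Ks and
I_CaL. The blocked cell is re-simulated to show the APD change.
"""

import cardiouq as cq
from cardiouq.biomarkers import extract
from cardiouq.protocols import DrugBlock, apply_drug_block, pic50_to_ic50

model = cq.get_model("tentusscher_2006_epi")
conc = 10.0  # uM
ic50_ks_cal = pic50_to_ic50(3.8)
blocks = [
    ("I_Kr", DrugBlock(conc, 29.0)),
    ("I_Na", DrugBlock(conc, 206.7)),
    ("I_Ks", DrugBlock(conc, ic50_ks_cal)),
    ("I_CaL", DrugBlock(conc, ic50_ks_cal)),
]
blocked = apply_drug_block(model.defaults, blocks)

for name, block in blocks:
    print(f"{name}: IC50 {block.ic50:6.1f} uM -> remaining fraction {block.factor:.3f}")

protocol = cq.make_protocol("long_pacing", duration=5000)  # 5 paced beats
control = extract(cq.run(model, None, protocol), 4000.0, 1000.0)
drug = extract(cq.run(model, blocked, protocol), 4000.0, 1000.0)
print(f"\nAPD90 control: {control.apd90:6.1f} ms")
print(f"APD90 at 10 uM: {drug.apd90:6.1f} ms  "
      f"(I_Kr block prolongs repolarisation by {drug.apd90 - control.apd90:+.1f} ms)")
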