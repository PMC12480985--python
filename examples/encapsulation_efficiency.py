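"""Quantify encapsulation efficiency for a simulated manufacturing campaign.

Seven nanoparticle batches each load 4 mg of drug.  The unencapsulated
fraction of each batch is assayed by HPLC against an internal standard:
a calibration line of peak-area ratio vs concentration ratio is fitted per
batch, the unknown is inverted through it, and EE(%) = 100 (total -
unencapsulated) / total.
"""

from imequant.pipeline import recover_batch_ee
from imequant.synth.chem import HplcBatchConfig

df = recover_batch_ee(HplcBatchConfig(seed=1))
print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print(f"\ncampaign mean EE: {df['ee_percent'].mean():.1f}%  "
      f"(truth drawn around 78.7 +/- 5.5%)")
print("Each row compares the EE recovered through the calibration pipeline")
print("with the batch's generating truth; R^2 confirms the line fit.")
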