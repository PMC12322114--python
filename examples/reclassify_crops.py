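"""Collapse a fine source crop legend onto the 16-class output catalogue.

The 28-class crop-type source map merges onto 16 output classes: all
cereals except maize and rice into CERE, eight minor classes into
OTHER.  A further 12-class legend serves comparisons with products that
use cruder crop typing.  Reclassification always conserves total area.
"""

import numpy as np
import pandas as pd

from irrigrid import AGGREGATED_SCHEME, DGPCM_SCHEME, reclassify_areas

rng = np.random.default_rng(0)
source = pd.DataFrame({"crop_code": list(DGPCM_SCHEME.mapping),
                       "aai_ha": rng.uniform(0, 100, 28).round(1)})
out16 = reclassify_areas(source, DGPCM_SCHEME)
out12 = reclassify_areas(out16, AGGREGATED_SCHEME)

print(f"source legend: {len(source)} classes, {source['aai_ha'].sum():.1f} ha")
print(f"output legend: {len(out16)} classes, {out16['aai_ha'].sum():.1f} ha")
print(f"aggregated legend: {len(out12)} classes, {out12['aai_ha'].sum():.1f} ha")
print(f"cereal classes merged into CERE: {DGPCM_SCHEME.sources_of('CERE')}")
print(f"minor classes merged into OTHER: {DGPCM_SCHEME.sources_of('OTHER')}")
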