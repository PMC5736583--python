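"""Convert a synthetic shadow-cast DIC image into a self-luminous image.

Builds a radial grating test chart, renders its DIC appearance
(inverted image plus 45° directional gradient), converts it back with
the composite directional Riesz-transform filter, and compares the
thresholded overlap with the plain Hilbert-transform variant.
"""

import numpy as np

from rtdic import (apply_filter, ht_filter, radial_grating, rtdic_convert,
                   synth_dic)


def jaccard_matched(out, truth, frac=0.5):
    b = truth > np.quantile(truth, 1 - frac)
    a = out > np.quantile(out, 1 - frac)
    return (a & b).sum() / (a | b).sum()


grating = radial_grating(shape=(128, 128), n_spokes=64)
dic = synth_dic(grating, theta=45.0)
composite = rtdic_convert(dic)                       # full composite filter
hilbert = apply_filter(dic, ht_filter((128, 128), 45.0))

j_comp = jaccard_matched(composite.data, grating.data)
j_ht = jaccard_matched(hilbert.data, grating.data)
print(f"thresholded overlap with ground truth (Jaccard):")
print(f"  composite Riesz filter : {j_comp:.3f}")
print(f"  Hilbert transform only : {j_ht:.3f}")
print("The composite restores spokes at every orientation; the Hilbert")
print("transform is blind to features along the 45° shear axis, so its")
print("overlap is far lower.")
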