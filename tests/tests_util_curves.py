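import numpy as np

from drbench.curves import FittedCurve


def make_fitted(front=1.0, back=0.0, slope=1.0, ec50=1.0, ic50=None):
    return FittedCurve(
        front=front, back=back, slope=slope, pec50=float(-np.log10(ec50)),
        p_value=0.0, ec50=float(ec50), ic50=ic50,
    )
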