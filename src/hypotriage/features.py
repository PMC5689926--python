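"""Feature extraction: from contoured structures to (f_bw, f_rw)."""

from __future__ import annotations

from .cohort import OverlapFeatures
from .errors import MissingStructureError
from .geometry import MarginSpec, StructureMask, expand_margin, fractional_overlap

__all__ = ["extract_features"]


def extract_features(
    bladder_wall: StructureMask,
    rectal_wall: StructureMask,
    *,
    ptv: StructureMask | None = None,
    ctv: StructureMask | None = None,
    margins: MarginSpec | None = None,
):
    """Compute a patient's overlap features from wall and target masks.

    The PTV may be supplied directly or derived from the CTV by margin
    expansion (clinical default margins when none are given).  Returns
    ``(features, ptv_source)`` where ``ptv_source`` is ``"supplied"`` or
    ``"expanded-from-ctv"``, plus the PTV used, as a third element.
    """
    if ptv is None:
        if ctv is None:
            raise MissingStructureError("either a PTV or a CTV must be provided")
        ptv = expand_margin(ctv, margins or MarginSpec())
        source = "expanded-from-ctv"
    else:
        source = "supplied"
    features = OverlapFeatures(
        f_bw=fractional_overlap(bladder_wall, ptv),
        f_rw=fractional_overlap(rectal_wall, ptv),
    )
    return features, source, ptv
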