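"""Missing-landmark estimation: bilateral mirroring, then TPS interpolation.

Stage 1 fills a missing landmark whose bilateral partner is preserved by
reflecting the partner across the least-squares midsagittal plane fitted to
the preserved midline landmarks.  Stage 2 fills the remaining gaps by
fitting a thin-plate spline from a complete template onto the preserved
landmarks and evaluating it at the template's positions of the missing ones.
"""

from __future__ import annotations

import numpy as np

from .geometry import LandmarkConfiguration, midline_plane, reflect_across_plane
from .scheme import LandmarkScheme
from .tps import SingularTPSError, tps_apply, tps_fit


class ImputationError(ValueError):
    """Too few preserved landmarks to resolve the missing ones."""


def impute_missing(
    config: LandmarkConfiguration,
    template: LandmarkConfiguration | np.ndarray,
    scheme: LandmarkScheme,
) -> LandmarkConfiguration:
    """Return a complete copy of ``config`` with missing landmarks estimated.

    Provenance of every filled landmark is recorded in the result's
    ``provenance`` array (``"mirrored"`` or ``"tps"``); the missing mask of
    the result is all-False.
    """
    tcoords = template.coords if isinstance(template, LandmarkConfiguration) else np.asarray(template, float)
    if isinstance(template, LandmarkConfiguration) and not template.is_complete:
        raise ImputationError("template must be complete")
    if tcoords.shape != config.coords.shape:
        raise ValueError("template landmark count does not match configuration")
    if config.is_complete:
        return config.copy()

    preserved = ~config.missing
    if preserved.sum() < 4:
        raise ImputationError(
            f"{config.specimen_id}: only {int(preserved.sum())} preserved landmarks; "
            "at least 4 required"
        )

    out = config.copy()
    coords = out.coords
    missing = out.missing.copy()
    provenance = out.provenance

    # stage 1 — mirror across the best-fit midline plane
    partner = scheme.partner()
    midline_ok = (~missing[np.array(scheme.midline, dtype=int)]).sum() >= 3 if scheme.midline else False
    if midline_ok:
        point, normal = midline_plane(coords, scheme, missing=missing)
        fillable = np.where(missing & ~missing[partner] & (partner != np.arange(len(missing))))[0]
        if fillable.size:
            coords[fillable] = reflect_across_plane(coords[partner[fillable]], point, normal)
            missing[fillable] = False
            provenance[fillable] = "mirrored"

    # stage 2 — TPS from the template onto the preserved landmarks
    remaining = np.where(missing)[0]
    if remaining.size:
        controls = np.where(~missing)[0]
        try:
            t = tps_fit(tcoords[controls], coords[controls])
        except SingularTPSError as err:
            raise ImputationError(
                f"{config.specimen_id}: cannot TPS-impute landmarks {remaining.tolist()}: {err}"
            ) from err
        coords[remaining] = tps_apply(t, tcoords[remaining])
        missing[remaining] = False
        provenance[remaining] = "tps"

    out.coords = coords
    out.missing = missing
    out.provenance = provenance
    return out
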