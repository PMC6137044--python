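"""Packaged parameter presets.

Each preset states the generating conditions of one emulated experiment:

* ``aptes_yeast`` — Can1-mCardinal tracked in APTES-glutaraldehyde
  immobilized yeast: 57% mobile at an apparent D of 5.1e-4 um^2/s, frames
  every 10 s.  The immobile coefficient sits at the detection edge; a small
  positive value (1e-5 um^2/s) keeps the mixture fit non-degenerate.
* ``cona_yeast`` — the same experiment on concanavalin-A coated glass:
  59% mobile, apparent D 5.4e-4 um^2/s.
* ``frap_guv_ld`` — lipid FRAP in the liquid-disordered phase of a GUV:
  82% recovery with a 196 ms halftime, 1-um-diameter bleach spot, 50 ms
  sampling for 6 s after 20 pre-bleach frames.

The tracking presets carry zero explicit localization error because the
quoted diffusion coefficients are apparent values that already include it.
"""

from __future__ import annotations

from .synthetic import TwoPopulationParams

TRACKING_PRESETS: dict[str, dict] = {
    "aptes_yeast": {
        "params": TwoPopulationParams(
            alpha_mobile=0.57,
            d_mobile_um2_s=5.1e-4,
            d_immobile_um2_s=1e-5,
            loc_error_nm=0.0,
        ),
        "lag_s": 10.0,
    },
    "cona_yeast": {
        "params": TwoPopulationParams(
            alpha_mobile=0.59,
            d_mobile_um2_s=5.4e-4,
            d_immobile_um2_s=1e-5,
            loc_error_nm=0.0,
        ),
        "lag_s": 10.0,
    },
}

FRAP_PRESETS: dict[str, dict] = {
    "frap_guv_ld": {
        "pre_level": 1.0,
        "bleach_depth": 0.6,
        "mobile_fraction": 0.82,
        "t_half_s": 0.196,
        "n_pre": 20,
        "n_post": 120,
        "dt_s": 0.05,
        "roi_radius_um": 0.5,
    },
}


def get_tracking_preset(name: str) -> dict:
    try:
        return TRACKING_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown tracking preset {name!r}; available: "
            f"{sorted(TRACKING_PRESETS)}"
        ) from None


def get_frap_preset(name: str) -> dict:
    try:
        return FRAP_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown FRAP preset {name!r}; available: {sorted(FRAP_PRESETS)}"
        ) from None
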