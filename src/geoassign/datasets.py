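"""Bundled reference data for the Cameroon-Nigeria chimpanzee panel.

Published values used as inputs: the ten reference sampling-site codes
and their biogeographic zones relative to the Sanaga River, the two study
boundary polygons, the cross-validation confusion matrix of the smoothed
assignment method over the georeferenced panel, and the per-animal query
summary (haplogroup, consensus site, continuous-assignment median
coordinates).  Site coordinates were never published, so sites here carry
zone labels only; coordinate-dependent analyses require a user-supplied
site file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assignment import BoundaryPolygon
from .io_formats import NORTH, SOUTH, TRANSITION

__all__ = [
    "SITE_CODES",
    "SITE_ZONES",
    "REFERENCE_PANEL_SIZE",
    "reference_confusion_matrix",
    "study_area_polygon",
    "central_range_polygon",
    "query_summary_table",
    "approximate_zone_polygons",
]

#: Reference sampling sites in table order.
SITE_CODES = ("ISFR", "GGNP", "AKZN", "CRNP", "MSSE", "MTCM", "MANB", "DEFR", "CMNP", "DJBR")

#: Biogeographic zone of each site relative to the Sanaga River.
SITE_ZONES = {
    "ISFR": NORTH,
    "GGNP": NORTH,
    "AKZN": NORTH,
    "CRNP": NORTH,
    "MSSE": NORTH,
    "MTCM": NORTH,
    "MANB": TRANSITION,
    "DEFR": SOUTH,
    "CMNP": SOUTH,
    "DJBR": SOUTH,
}

# Leave-one-out cross-validation assignment counts for the georeferenced
# panel: rows = true site, columns = assigned site.
_CONFUSION_COUNTS = [
    # ISFR GGNP AKZN CRNP MSSE MTCM MANB DEFR CMNP DJBR
    [3, 0, 0, 0, 1, 0, 0, 0, 0, 0],  # ISFR
    [0, 6, 1, 0, 1, 2, 0, 0, 0, 0],  # GGNP
    [0, 1, 4, 2, 3, 1, 0, 0, 0, 0],  # AKZN
    [0, 0, 1, 5, 0, 1, 0, 0, 0, 1],  # CRNP
    [0, 1, 1, 0, 5, 1, 0, 0, 0, 0],  # MSSE
    [0, 0, 1, 0, 0, 10, 0, 0, 0, 0],  # MTCM
    [0, 0, 0, 0, 0, 1, 4, 4, 1, 0],  # MANB
    [0, 0, 0, 1, 0, 0, 2, 4, 0, 1],  # DEFR
    [0, 0, 0, 0, 0, 0, 0, 0, 5, 3],  # CMNP
    [0, 1, 0, 0, 0, 0, 0, 3, 2, 4],  # DJBR
]

#: Stated size of the georeferenced panel; the tabulated assignments sum
#: to 88, two more, and the discrepancy is preserved rather than corrected.
REFERENCE_PANEL_SIZE = 86


def reference_confusion_matrix() -> pd.DataFrame:
    """Published cross-validation confusion matrix (true x assigned counts)."""
    return pd.DataFrame(_CONFUSION_COUNTS, index=list(SITE_CODES), columns=list(SITE_CODES))


# Study-area boundary across Cameroon and Nigeria (lat, lon).
_STUDY_AREA_VERTICES = (
    (9.01, 2.79),
    (7.80, 15.50),
    (6.03, 14.54),
    (3.73, 15.32),
    (1.71, 16.16),
    (2.26, 9.83),
    (3.96, 9.17),
    (4.42, 5.84),
    (6.22, 4.88),
    (6.47, 2.78),
    (9.01, 2.79),
)

# Boundary covering the central-African subspecies range south of the
# Sanaga, used for the negative-control continuous assignments (lat, lon).
_CENTRAL_RANGE_VERTICES = (
    (3.76, 9.61),
    (4.29, 11.29),
    (4.48, 13.63),
    (4.14, 16.30),
    (3.98, 18.59),
    (1.66, 18.10),
    (-0.57, 17.73),
    (-2.16, 16.32),
    (-4.33, 15.26),
    (-5.96, 12.43),
    (-4.48, 11.85),
    (-3.45, 10.57),
    (-1.87, 9.33),
    (-0.79, 8.92),
    (0.35, 9.48),
    (2.21, 9.91),
    (3.13, 9.99),
    (3.76, 9.61),
)


def study_area_polygon() -> BoundaryPolygon:
    """Cameroon-Nigeria habitat boundary used by the continuous assignments."""
    return BoundaryPolygon(_STUDY_AREA_VERTICES)


def central_range_polygon() -> BoundaryPolygon:
    """Central-African range boundary used by the negative-control test."""
    return BoundaryPolygon(_CENTRAL_RANGE_VERTICES)


# Per-animal published origin estimates: haplogroup, consensus site of the
# smoothed assignment, median coordinates and region of the continuous
# assignment.
_QUERY_ROWS = [
    ("LWC001", "1b", "MTCM", NORTH, 5.69426, 10.98525, NORTH),
    ("LWC002", "1b", "MTCM", NORTH, 4.79855, 9.2901, NORTH),
    ("LWC003", "1b", "MTCM", NORTH, 5.88904, 10.14165, NORTH),
    ("LWC004", "1b", "GGNP", NORTH, 6.06406, 10.804, NORTH),
    ("LWC005", "1b", "MSSE", NORTH, 6.01814, 9.33696, NORTH),
    ("LWC006", "1b", "MTCM", NORTH, 6.16266, 9.770035, NORTH),
    ("LWC007", "1b", "GGNP", NORTH, 6.4109, 10.4424, NORTH),
    ("LWC008", "1b", "MTCM", NORTH, 5.508405, 10.144, NORTH),
    ("LWC009", "1b", "MSSE", NORTH, 6.02645, 10.4546, NORTH),
    ("LWC010", "1b", "GGNP", NORTH, 6.686045, 11.5976, NORTH),
    ("LWC011", "1b", "MTCM", NORTH, 4.999935, 9.59359, NORTH),
    ("LWC012", "1b", "GGNP", NORTH, 6.387525, 10.6643, NORTH),
    ("LWC014", "1b", "GGNP", NORTH, 6.171715, 11.5504, NORTH),
    ("LWC017", "1b", "GGNP", NORTH, 6.20374, 11.4116, NORTH),
    ("LWC018", "1b", "MTCM", NORTH, 5.71996, 9.154565, NORTH),
    ("LWC019", "1b", "GGNP", NORTH, 6.819025, 10.63615, NORTH),
    ("LWC021", "1b", "GGNP", NORTH, 6.78872, 11.53365, NORTH),
    ("LWC023", "1b", "MSSE", NORTH, 5.784825, 10.3854, NORTH),
    ("LWC024", "1b", "MTCM", NORTH, 4.15989, 9.14837, NORTH),
    ("LWC026", "1b", "MSSE", NORTH, 5.74762, 10.60665, NORTH),
    ("LWC028", "1b", "MTCM", NORTH, 4.3105, 9.169405, NORTH),
    ("LWC030", "1b", "MTCM", NORTH, 5.691485, 10.45, NORTH),
    ("LWC033", "1b", "MTCM", NORTH, 5.88719, 9.870615, NORTH),
    ("LWC034", "1b", "AKZN", NORTH, 6.09503, 11.2155, NORTH),
    ("LWC036", "1b", "MTCM", NORTH, 5.709555, 10.8607, NORTH),
    ("LWC038", "1b", "MSSE", NORTH, 5.240895, 10.1503, NORTH),
    ("LWC041", "1b", "MTCM", NORTH, 5.97631, 9.97306, NORTH),
    ("LWC043", "1b", "GGNP", NORTH, 6.637165, 10.9659, NORTH),
    ("LWC044", "1b", "MTCM", NORTH, 6.04163, 9.87016, NORTH),
    ("LWC045", "1b", "MTCM", NORTH, 5.55618, 9.42, NORTH),
    ("LWC046", "1b", "MTCM", NORTH, 5.767895, 10.37835, NORTH),
    ("LWC016", "1b", "MANB", NORTH, 5.616985, 11.6057, TRANSITION),
    ("LWC027", "2a", "DJBR", SOUTH, 3.47309, 12.80025, SOUTH),
    ("LWC031", "2a", "DJBR", SOUTH, 3.933035, 13.092, SOUTH),
    ("LWC032", "2a", "CMNP", SOUTH, 3.65541, 11.2014, SOUTH),
    ("LWC040", "2a", "MANB", NORTH, 5.366435, 11.657, TRANSITION),
    ("LWC015", "2b", "CRNP", NORTH, 5.947675, 11.5971, TRANSITION),
    ("LWC025", "2c", "DJBR", SOUTH, 5.077715, 11.7409, TRANSITION),
    ("LWC013", "2c", "CMNP", SOUTH, 3.578515, 12.5198, SOUTH),
    ("LWC020", "2c", "CMNP", SOUTH, 3.364205, 12.05345, SOUTH),
    ("LWC022", "2c", "DJBR", SOUTH, 3.3743, 12.344, SOUTH),
    ("LWC029", "2c", "DJBR", SOUTH, 4.137805, 12.88305, SOUTH),
    ("LWC035", "2c", "DJBR", SOUTH, 4.54397, 12.2347, SOUTH),
    ("LWC037", "2c", "CMNP", SOUTH, 4.33148, 11.3812, SOUTH),
    ("LWC042", "2c", "DJBR", SOUTH, 3.38591, 12.71325, SOUTH),
    ("LWC039", "2c", "MSSE", NORTH, 4.7324, 10.4764, NORTH),
]


def query_summary_table() -> pd.DataFrame:
    """Published per-animal origin estimates for the 46 rescued chimpanzees."""
    return pd.DataFrame(
        _QUERY_ROWS,
        columns=[
            "sample_id",
            "haplogroup",
            "sam_site",
            "sam_region",
            "cam_lat",
            "cam_lon",
            "cam_region",
        ],
    ).set_index("sample_id")


def approximate_zone_polygons(pad: float = 0.5) -> dict[str, BoundaryPolygon]:
    """Rough rectangles around the published coordinate clusters per zone.

    APPROXIMATE by construction: the source study never defines zone
    boundary geometry, so these are padded bounding boxes of the published
    per-zone coordinates.  They can overlap; supply real zone polygons for
    any serious containment analysis.
    """
    df = query_summary_table()
    out: dict[str, BoundaryPolygon] = {}
    for zone, grp in df.groupby("cam_region"):
        lat_lo, lat_hi = grp["cam_lat"].min() - pad, grp["cam_lat"].max() + pad
        lon_lo, lon_hi = grp["cam_lon"].min() - pad, grp["cam_lon"].max() + pad
        out[zone] = BoundaryPolygon(
            ((lat_lo, lon_lo), (lat_lo, lon_hi), (lat_hi, lon_hi), (lat_hi, lon_lo))
        )
    return out
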