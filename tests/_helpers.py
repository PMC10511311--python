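"""Shared table builders for the test suite."""


def make_reach_row(reach_id="r0", q=4.0, slope=0.001, length_m=5000.0,
                   elevation_m=100.0, latitude=45.0, t_air=15.0,
                   ice_free=1.0, dry=0.0, q_cv=0.3, stream_order=1,
                   basin_group="bg0", longitude=10.0):
    """One-reach wide table row with constant monthly values."""
    row = {"reach_id": reach_id, "downstream_id": "", "length_m": length_m,
           "slope": slope, "elevation_m": elevation_m,
           "stream_order": stream_order, "basin_group": basin_group,
           "latitude": latitude, "longitude": longitude, "q_cv": q_cv}
    for m in range(1, 13):
        row[f"q_{m:02d}"] = q
        row[f"ice_{m:02d}"] = ice_free
        row[f"dry_{m:02d}"] = dry
        row[f"tair_{m:02d}"] = t_air
    return row
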