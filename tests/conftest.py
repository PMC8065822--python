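import numpy as np
import pytest

from endemap.geo import GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_grid():
    """10 x 10 grid of 1-km cells anchored at the origin."""
    return GridSpec(0.0, 0.0, 1.0, 10, 10)


@pytest.fixture
def square_patches_geojson(tmp_path):
    """A 2x2 mosaic of 1-degree squares covering [0,2]x[0,2] lon/lat."""
    import json

    def sq(x0, y0):
        return {
            "type": "Polygon",
            "coordinates": [[[x0, y0], [x0 + 1, y0], [x0 + 1, y0 + 1], [x0, y0 + 1], [x0, y0]]],
        }

    features = [
        {"type": "Feature", "properties": {"id": f"E{k}", "name": f"sq{k}"}, "geometry": sq(x, y)}
        for k, (x, y) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)])
    ]
    path = tmp_path / "patches.geojson"
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path
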