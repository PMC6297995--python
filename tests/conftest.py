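import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from ctvlt import synthetic_data as sd  # noqa: E402


@pytest.fixture(scope="session")
def abdomen_phantom_256():
    return sd.generate_phantom(sd.SUBSETS["abdomen_thick"], seed=42, size=256)


@pytest.fixture(scope="session")
def chest_phantom_256():
    return sd.generate_phantom(sd.SUBSETS["chest_thick"], seed=43, size=256)


@pytest.fixture(scope="session")
def noise_image_128():
    """Incompressible HU raster: every CR in (2, 40) is reachable."""
    from ctvlt.dicom_io import AcquisitionMeta, CTImage

    rng = np.random.default_rng(7)
    px = rng.integers(-1000, 1000, (128, 128)).astype(np.int16)
    meta = AcquisitionMeta(
        effective_mas=120.0,
        section_thickness_mm=4.0,
        fov_mm=300.0,
        recon_filter="soft-tissue",
        body_part="abdomen",
    )
    return CTImage(pixels=px, meta=meta, image_id="noise128")


@pytest.fixture(scope="session")
def design_row_sampler():
    """Design rows with independent predictors (no phantom rendering)."""
    from ctvlt.vlt_model import DesignRow

    def sample(n, seed):
        rng = np.random.default_rng(seed)
        return [
            DesignRow(
                image_sd=rng.uniform(40, 90),
                image_entropy=rng.uniform(3, 7),
                percentage_lf=rng.uniform(40, 95),
                variation_hf=rng.uniform(1, 13),
                visual_complexity=rng.uniform(0.15, 0.75),
                effective_mas=rng.uniform(20, 250),
                st=float(rng.choice([2.0, 3.0, 4.0])),
                fov=rng.uniform(240, 390),
                filter_sharp=int(rng.integers(0, 2)),
            )
            for _ in range(n)
        ]

    return sample
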