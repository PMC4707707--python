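import pytest

from cardiobench.geometry import EllipsoidSpec, generate_ventricle_mesh


@pytest.fixture(scope="session")
def ventricle_mesh_481():
    return generate_ventricle_mesh(EllipsoidSpec(4, 8, 2, order=1))
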