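from pathlib import Path

import pytest
import yaml

from testisscreen.expression import ClassificationRule
from testisscreen.simulate import BundleConfig, generate_bundle


def small_config(**overrides) -> BundleConfig:
    """A scaled-down bundle for fast unit tests (same rates, fewer genes)."""
    cfg = BundleConfig(
        n_source_genes=2000,
        n_testis_exclusive=60,
        n_testis_predominant=60,
        n_background_intermediate=400,
        n_curated=80,
        n_go_terms=40,
        go_term_size=(5, 40),
        n_de=30,
        n_background_focal=300,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config(), seed=123)


@pytest.fixture(scope="session")
def rule():
    return ClassificationRule()


def write_config(bundle_dir, out_dir, cfg: BundleConfig,
                 drop=(), **overrides) -> Path:
    """Write a pipeline YAML config pointing at a written bundle."""
    bundle_dir = Path(bundle_dir)
    raw = {
        "species": {
            "source": cfg.source_species,
            "intermediate": cfg.intermediate_species,
            "focal_target": cfg.focal_target,
        },
        "inputs": {
            "source_expression": str(bundle_dir / "source_expression.tsv"),
            "source_orthologs": str(
                bundle_dir / "orthologs_source_to_intermediate.tsv"
            ),
            "intermediate_expression": str(
                bundle_dir / "intermediate_expression.tsv"
            ),
            "phenotypes": str(bundle_dir / "phenotypes.tsv"),
            "target_orthologs": {
                sp: str(bundle_dir / f"orthologs_intermediate_to_{sp}.tsv")
                for sp in cfg.target_species
            },
            "curated_list": str(bundle_dir / "curated_list.tsv"),
            "go_annotations": str(bundle_dir / "go_annotations.tsv"),
            "counts": str(bundle_dir / "counts.tsv"),
            "conditions": str(bundle_dir / "conditions.tsv"),
            "ct_table": str(bundle_dir / "ct_table.tsv"),
        },
        "output_dir": str(out_dir),
    }
    for key in drop:
        raw["inputs"].pop(key, None)
    for dotted, value in overrides.items():
        section, _, leaf = dotted.partition(".")
        if leaf:
            raw.setdefault(section, {})[leaf] = value
        else:
            raw[section] = value
    path = Path(bundle_dir).parent / "config.yaml"
    path.write_text(yaml.safe_dump(raw), encoding="utf-8")
    return path
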