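import pytest

from ablm import (
    AntibodySequence,
    CorruptionConfig,
    GeneratorConfig,
    TrainConfig,
    build_model,
    generate,
    tiny_config,
    toy_germlines,
    train,
)

@pytest.fixture(scope="session")
def toy_db():
    return toy_germlines()


@pytest.fixture(scope="session")
def heavy5(toy_db):
    """Five heavy-chain toy alleles, the repertoire used across the suite."""
    return toy_db.subset(toy_db.alleles("heavy")[:5])


@pytest.fixture(scope="session")
def repertoire(heavy5):
    """A small mixed repertoire (default truncation/ambiguity profile)."""
    cfg = GeneratorConfig(n_sequences=300, chain="heavy", germlines=heavy5, seed=3)
    return generate(cfg)


@pytest.fixture(scope="session")
def untrained_tiny():
    return build_model(tiny_config(), 0)


@pytest.fixture(scope="session")
def trained_tiny(heavy5):
    """Tiny encoder trained under the suite's reference conditions:
    2,000 synthetic heavy sequences from 5 germline alleles at 3% mutation,
    drawn with the generator's default N-terminal truncation profile (as in
    real repertoire data, where most reads are truncated), 30 epochs.
    Shared across tests because training is the expensive step. Returns the
    model plus its training/held-out corpora."""
    gen = GeneratorConfig(
        n_sequences=2200,
        chain="heavy",
        germlines=heavy5,
        mutation_rate=0.03,
        ambiguous_rate=0.0,
        seed=7,
    )
    seqs, gt = generate(gen)
    train_seqs, held_out = seqs[:2000], seqs[2000:]
    model = build_model(tiny_config(dropout=0.0), 1)
    trace = train(
        model,
        train_seqs,
        TrainConfig(epochs=30, batch_size=64, peak_lr=1e-3, seed=0),
        CorruptionConfig(),
    )
    return {
        "model": model,
        "train_seqs": train_seqs,
        "held_out": held_out,
        "truth": gt,
        "germlines": heavy5,
        "trace": trace,
    }


@pytest.fixture
def seq():
    def make(residues, id="s1", chain="heavy", numbering=None):
        return AntibodySequence(id=id, chain=chain, residues=residues, numbering=numbering)

    return make
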