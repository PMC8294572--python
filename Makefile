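.PHONY: test acceptance full-validation

test:
	python -m pytest -q tests/

acceptance:
	python scripts/acceptance.py --seed 1 --out results/acceptance.json

# Overnight job: the complete design grids at 10,000 replicates per design.
# Not part of the regular test run; see docs/methods.md for what it produces.
full-validation:
	python scripts/full_validation.py --replicates 10000 --seed 1 \
		--out-dir results/full_validation
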