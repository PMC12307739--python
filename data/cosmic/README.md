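# COSMIC signature matrix (not included)

The signature-composition check
(`tests/test_acceptance.py::test_cosmic_v33_signature_cgtg_fractions`) and
`fdeam.biomarker_eval.signature_cgtg_fraction` analyses of real reference
signatures need the official COSMIC v3.3 SBS probability matrix. COSMIC
reference data is distributed under its own terms and is therefore not
bundled with this package.

To enable the check, download the exome-or-genome SBS matrix (e.g.
`COSMIC_v3.3.1_SBS_GRCh37.txt`: 96 context-labeled rows, one column per
signature, tab-separated) from the COSMIC mutational-signatures site and
place it in this directory. Any filename matching `COSMIC_v3*SBS*.txt` is
picked up. Note the genome build of the matrix you supply: the CG>TG
content of a signature differs slightly between builds because the
trinucleotide background differs.
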