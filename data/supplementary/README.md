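Place the published baleen-whale CHR2 call set here to enable the
full-data validation test:

    data/supplementary/<name>.vcf   (or .vcf.gz)

The file is distributed as supplementary data of the original study and is
not redistributed with this package. Without it, the test
`test_published_call_set_reproduces_summary_numbers` fails with a pointer to
this directory; all other tests are self-contained.
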