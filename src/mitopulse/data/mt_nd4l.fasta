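>sp|P03901|NU4LM_HUMAN NADH-ubiquinone oxidoreductase chain 4L GN=MT-ND4L
MPLIYMNIMLAFTISLLGMLVYRSHLMSSLLCLEGMMLSLFIMATLMTLNTHSLLANIVP
IAMLVFAACEAAVGLALLVSISNTYGLDYVHNLNLLQC
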