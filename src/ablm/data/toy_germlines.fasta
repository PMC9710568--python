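>IGHV-SYN1*01 chain=heavy synthetic toy allele (hand-constructed, not an IMGT record)
EVQLVESGG.GLVQPGGSLRLSCAASGFTF....SSYAWVRQAPGKGLEWVSAISISGSGG..STYYADSVK.GRFTISRDNSKNTLYLQMNSLRAEDTAVYYCARDYSG...GMDYWGQGTLVTVSS
>IGHV-SYN2*01 chain=heavy synthetic toy allele (hand-constructed, not an IMGT record)
EVQYVESGS.GLVQFGGTLRLSCAASGFTF....SSYAWVRQAPGKGLEWSSAISISGDHG..STYYADSTK.MRFTISRDNSKNTKYLQMNPLRAEDTAVYYCARDYSG...GMNYVGQGTLVTVHS
>IGHV-SYN3*01 chain=heavy synthetic toy allele (hand-constructed, not an IMGT record)
EVQLVESGG.GLVQPWGSLRLSGAASGFYF....SSYFWVRQAPHKGLEWVSAISISGDGG..STYCADSVK.GRGTPSRDNSKNTLYLQANSLRAELTAVYYCARDYSG...VMQYWGQNTLVTVSS
>IGHV-SYN4*01 chain=heavy synthetic toy allele (hand-constructed, not an IMGT record)
ECQLVESGG.GLVQPGGSLLLSAAASGFTF....SSYAWVRVHPSKGLEWVAAISIWGSGG..STYYADSVK.GRFTIHRDNSKNTAYLQMNSERAEDTAVYYCARDYNG...GCDYWGQGTLGTVSS
>IGHV-SYN5*01 chain=heavy synthetic toy allele (hand-constructed, not an IMGT record)
GVQLVESFG.GLVQLGGVLRLSHAASGFTF....SSYAWVRQAPGKGLEWGSAIWISGSGG..STYYADSVK.GRFTYLRDNSKNTLYLRMNSLRGEDTAVYYCARDYSW...GMKYWGQQTLVTVSS
>IGHV-SYN6*01 chain=heavy synthetic toy allele (hand-constructed, not an IMGT record)
EVQLPESPG.GLVDPGGSLRLSCAASGFTF....SSYAWLRRAMGKGLEWVSLISISGDGG..STYYADSVK.GRFTISRDNSKNTLYLQMNLSRAEDTAVYYCARFYMV...GMDYWGQGTWVTVSS
>IGKV-SYN1*01 chain=light synthetic toy allele (hand-constructed, not an IMGT record)
DIQMTQSPSS...LSASVGDRVTITCQSI......SNYLAWYQQKPGKAPKLLIYAAS.......SLQSGVP.SRFSGSG..SGTDFTLTISSLQPEDFATYYCQQSYS....TPLTFGQGTKVEIKR
>IGKV-SYN2*01 chain=light synthetic toy allele (hand-constructed, not an IMGT record)
DKQMTQSPFS...LSASWGDRHTITCQSH......SNYLAWYQPKPGKAPKLLIYIAS.......SLQSGVP.SRFSGSP..SLTDFTLNISSLQPEDFATYYCQQSYC....FPLTFGQGTKVKITR
>IGKV-SYN3*01 chain=light synthetic toy allele (hand-constructed, not an IMGT record)
DIQMTQCPSS...LSASVGDIVTITCESI......SNYLAWYQDRAVKAPKTQIYAAS.......SGQSGVP.SRFSGSG..SGTPFTLTISSLQPEDFATYYCQQSIS....TPNTFGQGTKVAIKR
>IGKV-SYN4*01 chain=light synthetic toy allele (hand-constructed, not an IMGT record)
DDYMTQSPSS...LSASVGDRVTPTCQSI......SNYLAWYQQKPGKQPKLLIYAAS.......SLKVGVP.SRFSGSV..IGTDFTDIMSSLQPEDFPTYYCQQSYT....TPLTFGQGTPVEIKR
>IGKV-SYN5*01 chain=light synthetic toy allele (hand-constructed, not an IMGT record)
DQQCTQSPSS...LSASVGDHVTKTIQSI......SNYSAWYQQKPGKAPKLLIYAAS.......SLQSGVP.SRISGST..SGYDFYLTISSLQPEDFATYVHQQSYS....TPLTFGQGTKVEIVH
>IGKV-SYN6*01 chain=light synthetic toy allele (hand-constructed, not an IMGT record)
DIQMCQSPSS...LSPSVGDRVTITCQSI......SNYLAWYQQKPGKAPKLLIYAAI.......SLQSGVM.SRFSGSG..SFTEFTIVASALQPDDFATYYCQQSYS....TPLTFGSMHKVEIKR
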