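child	parent
GO:0031430	GO:0030017
GO:0031672	GO:0030017
GO:0030017	GO:0030016
GO:0030016	GO:0043292
GO:0043292	GO:0005856
GO:0005856	GO:0005737
GO:0005737	GO:0005622
GO:0005622	GO:0005575
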