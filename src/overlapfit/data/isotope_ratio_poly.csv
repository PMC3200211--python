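l,beta0,beta1,beta2,beta3,beta4,sigma_sq
2,-2.5835,3.2954,-1.7098,0.4594,-0.0466,0.0035
3,-2.6283,2.3416,-1.0856,0.2772,-0.0274,0.0008
4,-2.9429,2.4265,-1.2003,0.3197,-0.0324,0.0006
5,-3.1161,2.3733,-1.1854,0.3176,-0.0323,0.0010
6,-3.2939,2.4299,-1.2464,0.3386,-0.0347,0.0012
7,-3.4508,2.4994,-1.3110,0.3600,-0.0372,0.0016
8,-3.6021,2.5967,-1.3932,0.3865,-0.0401,0.0019
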